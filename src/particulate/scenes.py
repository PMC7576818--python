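"""Synthetic tile-scan scenes with known ground truth.

The generator emulates the statistical structure of particulate fallout on
an exposed coated slide: sparse dark particles on a bright background (a
few per mm^2), three size classes with truncated log-normal area laws
(fine 0.5-50 um^2, coarse 50-1500 um^2 with a mode near 155 um^2,
macroscopic >1500 um^2), a morphotype mix per class (flat convex polygons,
curved ribbon fibers with high elongation, round and dividing
microparticles), occasional bright drying halos, a linear illumination
gradient, additive Gaussian sensor noise, and rare macroscopic occluders
that must trip frame rejection.

Every planted particle is recorded in a :class:`SceneTruth` table so that
detection and statistics can be validated against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import norm
from skimage.draw import polygon as draw_polygon

from particulate.detection import ScanConfig, TileStack

__all__ = [
    "SizeLaw",
    "SceneSpec",
    "SceneTruth",
    "sample_truth",
    "render_tiles",
    "truncated_lognormal_mean",
    "CrowdedFieldError",
]


class CrowdedFieldError(RuntimeError):
    """Raised when hard-core placement cannot fit all requested particles."""


@dataclass(frozen=True)
class SizeLaw:
    """Truncated log-normal area law, parameterised by its mode.

    ``mode`` is the most probable area (um^2) of the *untruncated*
    log-normal, ``sigma_log`` the shape parameter (standard deviation of
    log-area), and ``lower``/``upper`` the hard truncation bounds (um^2).
    Parameterising by the mode makes the peak of the size histogram
    directly plantable.
    """

    mode: float
    sigma_log: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.mode < self.upper):
            raise ValueError(
                f"require 0 < lower < mode < upper, got "
                f"({self.lower}, {self.mode}, {self.upper})"
            )
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")

    @property
    def mu_log(self) -> float:
        """Log-scale location: mode = exp(mu - sigma^2)."""
        return math.log(self.mode) + self.sigma_log**2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` areas by inverse-CDF sampling of the truncated law."""
        if n == 0:
            return np.empty(0)
        if self.sigma_log == 0:
            return np.full(n, self.mode)
        mu, s = self.mu_log, self.sigma_log
        lo = norm.cdf((math.log(self.lower) - mu) / s)
        hi = norm.cdf((math.log(self.upper) - mu) / s)
        u = rng.uniform(lo, hi, n)
        return np.exp(mu + s * norm.ppf(u))

    def mean(self) -> float:
        return truncated_lognormal_mean(
            self.mode, self.sigma_log, self.lower, self.upper
        )


def truncated_lognormal_mean(
    mode: float, sigma_log: float, lower: float, upper: float
) -> float:
    """Expected area (um^2) of a truncated log-normal given by its mode.

    For the untruncated law the identity ``mean = mode * exp(1.5 sigma^2)``
    holds; truncation to ``[lower, upper]`` rescales it by the ratio of
    Gaussian tail masses shifted by sigma:

    ``E = mode * exp(1.5 s^2) * [Phi(b - s) - Phi(a - s)] / [Phi(b) - Phi(a)]``

    with ``a = (ln lower - mu)/s``, ``b = (ln upper - mu)/s`` and
    ``mu = ln(mode) + s^2``.
    """
    if not (0 < lower < mode < upper):
        raise ValueError(
            f"require 0 < lower < mode < upper, got ({lower}, {mode}, {upper})"
        )
    if sigma_log < 0:
        raise ValueError("sigma_log must be non-negative")
    if sigma_log < 1e-9:
        return float(mode)
    mu = math.log(mode) + sigma_log**2
    s = sigma_log
    a = (math.log(lower) - mu) / s
    b = (math.log(upper) - mu) / s
    num = norm.cdf(b - s) - norm.cdf(a - s)
    den = norm.cdf(b) - norm.cdf(a)
    return float(math.exp(mu + s**2 / 2) * num / den)


_DEFAULT_SIZE_LAWS: dict[str, SizeLaw] = {
    "fine": SizeLaw(mode=2.0, sigma_log=1.0, lower=0.5, upper=50.0),
    "coarse": SizeLaw(mode=155.0, sigma_log=0.7, lower=50.0, upper=1500.0),
    "macroscopic": SizeLaw(mode=3000.0, sigma_log=0.5, lower=1500.0,
                           upper=50000.0),
}

# Morphotype probabilities per size class. Coarse particles are mostly
# flat polygonal flakes; ribbon fibers dominate the macroscopic class;
# fine particles are round or dividing microparticles.
_DEFAULT_MORPHOTYPE_MIX: dict[str, dict[str, float]] = {
    "fine": {"round": 0.7, "dividing": 0.3},
    "coarse": {"polygon": 0.85, "round": 0.10, "fiber": 0.05},
    "macroscopic": {"fiber": 0.5, "polygon": 0.3, "round": 0.2},
}

# Observed average densities: 1.6 coarse and 3.3 fine particles per mm^2;
# macroscopic particles are two orders of magnitude rarer (~180 counted
# over ~2900 mm^2 of surveyed surface).
_DEFAULT_DENSITIES: dict[str, float] = {
    "fine": 3.3,
    "coarse": 1.6,
    "macroscopic": 0.06,
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic lamella scene.

    The defaults reproduce the survey conditions the analysis assumes:
    field of ~243 mm^2 (the per-lamella scanned area inferred from counts
    over densities), densities of 3.3 / 1.6 / 0.06 particles per mm^2 for
    the fine / coarse / macroscopic classes, truncated log-normal size
    laws with modes 2 / 155 / 3000 um^2, background grey 200 with a
    particle contrast of 160 on the blue channel, and sensor noise at a
    contrast-to-noise ratio of 5.
    """

    field_width_mm: float = 15.6
    field_height_mm: float = 15.6
    density_per_class: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DENSITIES))
    size_law_per_class: Mapping[str, SizeLaw] = field(
        default_factory=lambda: dict(_DEFAULT_SIZE_LAWS))
    morphotype_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in _DEFAULT_MORPHOTYPE_MIX.items()})
    background_level: float = 200.0
    particle_contrast: float = 160.0
    noise_sigma: float = 32.0
    gradient_amplitude: float = 10.0
    halo_fraction: float = 0.1
    halo_amplitude: float = 30.0
    halo_width_um: float = 1.5
    occluder_count: int = 0
    occluder_cover_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_width_mm <= 0 or self.field_height_mm <= 0:
            raise ValueError("field dimensions must be positive")
        for cls, d in self.density_per_class.items():
            if d < 0:
                raise ValueError(f"density for class {cls!r} is negative")
            if d > 0 and cls not in self.size_law_per_class:
                raise ValueError(f"no size law for populated class {cls!r}")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must lie in [0, 255]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 <= self.halo_fraction <= 1:
            raise ValueError("halo_fraction must lie in [0, 1]")
        if not 0 < self.occluder_cover_fraction < 1:
            raise ValueError("occluder_cover_fraction must lie in (0, 1)")
        for cls, mix in self.morphotype_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"morphotype probabilities for {cls!r} sum to {total}, "
                    "expected 1"
                )

    @property
    def area_mm2(self) -> float:
        return self.field_width_mm * self.field_height_mm


@dataclass
class SceneTruth:
    """Planted-particle table for one synthetic scene.

    ``particles`` rows are ``(id, x_um, y_um, true_area_um2, morphotype,
    has_halo)``; ``occluders`` rows are ``(x_um, y_um, cover_fraction)``
    where the cover fraction is resolved to a pixel extent at render time
    (the occluder is drawn centred on the tile containing its centroid).
    """

    particles: list[tuple[int, float, float, float, str, bool]]
    occluders: list[tuple[float, float, float]]
    spec: SceneSpec

    def __len__(self) -> int:
        return len(self.particles)

    def areas(self) -> np.ndarray:
        return np.array([p[3] for p in self.particles])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.particles,
            columns=["id", "x_um", "y_um", "area_um2", "morphotype",
                     "has_halo"],
        )


_CLASS_ORDER = ("macroscopic", "coarse", "fine")  # largest first


def sample_truth(spec: SceneSpec, max_attempts: int = 1000) -> SceneTruth:
    """Draw a ground-truth particle configuration for ``spec``.

    Counts per class are Poisson with mean density x field area; areas
    follow each class's truncated log-normal; positions are uniform under
    a hard-core constraint (centre-to-centre distance at least twice the
    larger equivalent radius of the pair). Placement proceeds from the
    largest particle down and rejection-samples each position up to
    ``max_attempts`` times before raising :class:`CrowdedFieldError`.
    Fully reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    w_um = spec.field_width_mm * 1000.0
    h_um = spec.field_height_mm * 1000.0

    drawn: list[tuple[float, str, bool]] = []  # (area, morphotype, halo)
    for cls in _CLASS_ORDER:
        dens = spec.density_per_class.get(cls, 0.0)
        n = int(rng.poisson(dens * spec.area_mm2)) if dens > 0 else 0
        if n == 0:
            continue
        law = spec.size_law_per_class[cls]
        areas = law.sample(n, rng)
        mix = spec.morphotype_mix.get(cls, {"round": 1.0})
        names = sorted(mix)
        probs = np.array([mix[m] for m in names])
        morphs = rng.choice(names, size=n, p=probs / probs.sum())
        halos = rng.random(n) < spec.halo_fraction
        drawn.extend(zip(areas.tolist(), morphs.tolist(), halos.tolist()))

    # hard-core placement, largest first so each new particle only needs
    # clearance 2 * r_placed from every already-placed (larger) one
    drawn.sort(key=lambda t: -t[0])
    placed_xy = np.empty((0, 2))
    placed_r = np.empty(0)
    particles: list[tuple[int, float, float, float, str, bool]] = []
    for pid, (area, morph, halo) in enumerate(drawn):
        r = math.sqrt(area / math.pi)
        ok = False
        for _ in range(max_attempts):
            x = rng.uniform(0, w_um)
            y = rng.uniform(0, h_um)
            if placed_xy.size:
                d2 = (placed_xy[:, 0] - x) ** 2 + (placed_xy[:, 1] - y) ** 2
                if np.any(d2 < (2 * np.maximum(placed_r, r)) ** 2):
                    continue
            ok = True
            break
        if not ok:
            raise CrowdedFieldError(
                f"could not place particle {pid} (area {area:.1f} um^2) "
                f"after {max_attempts} attempts; field too crowded"
            )
        placed_xy = np.vstack([placed_xy, [x, y]])
        placed_r = np.append(placed_r, r)
        particles.append((pid, float(x), float(y), float(area), morph,
                          bool(halo)))

    occluders = [
        (float(rng.uniform(0, w_um)), float(rng.uniform(0, h_um)),
         spec.occluder_cover_fraction)
        for _ in range(spec.occluder_count)
    ]
    return SceneTruth(particles=particles, occluders=occluders, spec=spec)


# ---------------------------------------------------------------------------
# shape rasterisation


def _stamp(canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray,
           value: np.ndarray | float, channel=slice(None)) -> None:
    h, w = canvas.shape[:2]
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    canvas[rows[ok], cols[ok], channel] = value


def _disk_pixels(cx: float, cy: float, r_px: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre rasterisation of a disk (mosaic pixel indices)."""
    r0 = int(math.floor(cy - r_px)) - 1
    r1 = int(math.ceil(cy + r_px)) + 1
    c0 = int(math.floor(cx - r_px)) - 1
    c1 = int(math.ceil(cx + r_px)) + 1
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    inside = (rr + 0.5 - cy) ** 2 + (cc + 0.5 - cx) ** 2 < r_px**2
    return rr[inside], cc[inside]


def _round_pixels(cx, cy, area_px, rng):
    r = math.sqrt(area_px / math.pi)
    return _disk_pixels(cx, cy, r)


def _dividing_pixels(cx, cy, area_px, rng):
    """Two overlapping equal disks (centre distance 1.2 r) with the
    requested union area; mimics a dividing microbial cell."""
    c = 1.2
    g = 2 * math.pi - 2 * math.acos(c / 2) + (c / 2) * math.sqrt(4 - c**2)
    r = math.sqrt(area_px / g)
    theta = rng.uniform(0, math.pi)
    dx, dy = (c * r / 2) * math.cos(theta), (c * r / 2) * math.sin(theta)
    r1, c1 = _disk_pixels(cx - dx, cy - dy, r)
    r2, c2 = _disk_pixels(cx + dx, cy + dy, r)
    pts = np.unique(np.stack([np.concatenate([r1, r2]),
                              np.concatenate([c1, c2])], axis=1), axis=0)
    return pts[:, 0], pts[:, 1]


def _polygon_pixels(cx, cy, area_px, rng):
    """Random convex 4-7-gon scaled to the requested area."""
    k = int(rng.integers(4, 8))
    ang = np.sort(rng.uniform(0, 2 * math.pi, k))
    rad = rng.uniform(0.6, 1.0, k)
    xs = rad * np.cos(ang)
    ys = rad * np.sin(ang)
    raw_area = 0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))
    scale = math.sqrt(area_px / raw_area)
    rows, cols = draw_polygon(cy + ys * scale, cx + xs * scale)
    if rows.size == 0:  # degenerate at very small areas
        return _disk_pixels(cx, cy, math.sqrt(area_px / math.pi))
    return rows, cols


def _fiber_pixels(cx, cy, area_px, rng):
    """Curved ribbon: disks stamped along a quadratic Bezier arc.

    The target aspect ratio (length/width) is drawn in [6, 12] so the
    measured elongation clears the fiber threshold of 5 even after the
    bend; the capsule area L*w + pi*(w/2)^2 matches the requested area.
    """
    aspect = rng.uniform(6.0, 12.0)
    w = math.sqrt(area_px / (aspect + math.pi / 4))
    length = aspect * w
    theta = rng.uniform(0, math.pi)
    ux, uy = math.cos(theta), math.sin(theta)
    # chord slightly shorter than the arc; perpendicular sag bends it
    half = 0.48 * length
    sag = 0.12 * length * rng.choice([-1.0, 1.0])
    p0 = np.array([cx - half * ux, cy - half * uy])
    p2 = np.array([cx + half * ux, cy + half * uy])
    p1 = np.array([cx - sag * uy, cy + sag * ux])
    t = np.linspace(0, 1, max(int(4 * length / w), 8))
    bez = (np.outer((1 - t) ** 2, p0) + np.outer(2 * t * (1 - t), p1)
           + np.outer(t**2, p2))
    pts = []
    for bx, by in bez:
        rr, cc = _disk_pixels(bx, by, w / 2)
        pts.append(np.stack([rr, cc], axis=1))
    allpts = np.unique(np.vstack(pts), axis=0)
    return allpts[:, 0], allpts[:, 1]


_SHAPE_FUNCS = {
    "round": _round_pixels,
    "dividing": _dividing_pixels,
    "polygon": _polygon_pixels,
    "fiber": _fiber_pixels,
}


def render_tiles(truth: SceneTruth, scan: ScanConfig,
                 metadata: Mapping | None = None) -> TileStack:
    """Rasterise a ground-truth scene into an 8-bit RGB tile stack.

    Particles are drawn darker than the background on all channels, with
    the strongest contrast on the blue channel (full ``particle_contrast``
    on blue, 60% of it on red/green). Halos are bright annuli hugging the
    particle boundary; occluders are large dark blobs centred on one tile;
    a linear horizontal illumination gradient and additive Gaussian noise
    (seeded from ``spec.seed``, independent of the truth draw) complete
    the scene. The mosaic is padded with background so tiles divide it
    exactly; the stack therefore covers at least the physical field.
    """
    if scan.pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    spec = truth.spec
    px = scan.pixel_size_um
    th, tw = scan.tile_shape_px
    w_px = int(math.ceil(spec.field_width_mm * 1000.0 / px))
    h_px = int(math.ceil(spec.field_height_mm * 1000.0 / px))
    n_rows = max(int(math.ceil(h_px / th)), 1)
    n_cols = max(int(math.ceil(w_px / tw)), 1)
    H, W = n_rows * th, n_cols * tw

    mosaic = np.full((H, W, 3), float(spec.background_level), dtype=np.float32)
    if spec.gradient_amplitude:
        grad = spec.gradient_amplitude * (
            np.arange(W, dtype=np.float32) / max(W - 1, 1) - 0.5)
        mosaic += grad[None, :, None]

    shape_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 1]))

    blue_val = spec.background_level - spec.particle_contrast
    rg_val = spec.background_level - 0.6 * spec.particle_contrast
    halo_w_px = max(int(round(spec.halo_width_um / px)), 2)

    for pid, x_um, y_um, area_um2, morph, has_halo in truth.particles:
        cx, cy = x_um / px, y_um / px
        area_px = area_um2 / px**2
        rows, cols = _SHAPE_FUNCS[morph](cx, cy, area_px, shape_rng)
        # recentre the rasterised shape so its pixel centroid coincides
        # with the planted position (pixel centres at index + 0.5)
        rows = rows + int(round(cy - 0.5 - rows.mean()))
        cols = cols + int(round(cx - 0.5 - cols.mean()))
        if has_halo:
            # bright annulus: disk shell around the shape's bounding circle
            r_eq = math.sqrt(area_px / math.pi)
            rr_o, cc_o = _disk_pixels(cx, cy, r_eq + 2 + halo_w_px)
            shell = np.ones(rr_o.size, dtype=bool)
            shape_set = set(zip(rows.tolist(), cols.tolist()))
            for i, (r_, c_) in enumerate(zip(rr_o.tolist(), cc_o.tolist())):
                if (r_, c_) in shape_set:
                    shell[i] = False
            _stamp(mosaic, rr_o[shell], cc_o[shell],
                   min(spec.background_level + spec.halo_amplitude, 255.0))
        _stamp(mosaic, rows, cols, rg_val, channel=slice(0, 2))
        _stamp(mosaic, rows, cols, blue_val, channel=2)

    for ox_um, oy_um, cover in truth.occluders:
        # centred on the tile containing the centroid so the blob covers
        # the requested fraction of exactly that tile
        trow = min(int(oy_um / px) // th, n_rows - 1)
        tcol = min(int(ox_um / px) // tw, n_cols - 1)
        cy = trow * th + th / 2
        cx = tcol * tw + tw / 2
        r_occ = math.sqrt(cover * th * tw / math.pi)
        rr, cc = _disk_pixels(cx, cy, r_occ)
        _stamp(mosaic, rr, cc, 20.0)

    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 2]))
        mosaic += noise_rng.normal(
            0.0, spec.noise_sigma, mosaic.shape).astype(np.float32)

    mosaic = np.clip(np.rint(mosaic), 0, 255).astype(np.uint8)

    tiles, positions = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            tiles.append(mosaic[r * th:(r + 1) * th, c * tw:(c + 1) * tw]
                         .copy())
            positions.append((r, c))
    meta = dict(metadata or {})
    meta.setdefault("scene_seed", spec.seed)
    return TileStack(tiles=tiles, positions=positions, metadata=meta,
                     scan=scan)
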