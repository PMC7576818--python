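"""Two-magnification particle detection in tile-scan brightfield mosaics.

The chain mirrors the workflow used for surveying particulate fallout on
coated glass slides: tiles with macroscopic occluders are rejected by an
intensity statistic, particles are segmented on the blue channel with a
constant global threshold, each candidate is refined with a local threshold
proportional to the mean of its crop, and areas/elongations are measured
from second central moments of the refined mask.

Conventions (fixed once, used everywhere):

* particles are *dark on bright*: a pixel belongs to a particle when its
  working-channel value is strictly below the threshold;
* mosaic coordinates are in micrometres, origin at the top-left corner of
  the tile grid, x rightward, y downward; a pixel's position is its centre,
  ``(index + 0.5) * pixel_size``;
* elongation is the major/minor axis ratio of the ellipse sharing the
  mask's second central moments (each pixel treated as a unit square, which
  adds 1/12 to the diagonal of the covariance matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure as skmeasure

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "TileStack",
    "ParticleRecord",
    "reject_frames",
    "segment_global",
    "refine_crop",
    "measure",
    "run_detection",
]


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition and segmentation parameters for one magnification.

    Parameters
    ----------
    zoom : {"low", "high"}
        Magnification regime. Low zoom surveys coarse particles
        (50-1500 um^2), high zoom fine particles (0.5-50 um^2).
    pixel_size_um : float
        Lateral sampling in micrometres per pixel. Defaults follow a
        1392x1040 camera with a x5 objective: 1.55 um/px at low zoom and
        0.155 um/px at high zoom; both map the minimum particle area of
        their regime to the same ~21 px footprint.
    global_threshold : int
        Constant grey-level threshold applied to the blue channel
        (8-bit scale); pixels strictly below it are particle candidates.
    rejection_k : float
        Multiplier of the stack-average per-tile standard deviation used
        by :func:`reject_frames`.
    min_area_um2, max_area_um2 : float
        Area bounds of the size regime surveyed at this zoom. Detection
        drops refined particles below ``min_area_um2``; ``max_area_um2``
        delimits the regime for the statistics layer and is not a
        detection cut (macroscopic particles are kept and classified).
    local_alpha : float
        Local refinement threshold as a fraction of the crop mean.
    crop_margin_px : int
        Padding added around a candidate bounding box before refinement.
    crop_channel : {"blue", "sum", None}
        Working channel for local refinement. ``None`` selects the zoom
        default: blue at low zoom, 8-bit-rescaled R+G+B sum at high zoom.
    tile_shape_px : (int, int)
        Tile height and width in pixels.
    """

    zoom: str = "low"
    pixel_size_um: float = 1.55
    global_threshold: int = 75
    rejection_k: float = 2.0
    min_area_um2: float = 50.0
    max_area_um2: float = 1500.0
    local_alpha: float = 0.6
    crop_margin_px: int = 10
    crop_channel: str | None = None
    tile_shape_px: tuple[int, int] = (260, 348)

    def __post_init__(self) -> None:
        if self.zoom not in ("low", "high"):
            raise ValueError(f"zoom must be 'low' or 'high', got {self.zoom!r}")
        if not 0 <= self.global_threshold <= 255:
            raise ValueError("global_threshold must lie in [0, 255]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("min_area_um2 must be smaller than max_area_um2")
        if not 0 < self.local_alpha <= 1:
            raise ValueError("local_alpha must lie in (0, 1]")
        if self.crop_channel not in (None, "blue", "sum"):
            raise ValueError("crop_channel must be 'blue', 'sum' or None")

    @classmethod
    def low_zoom(cls, **overrides) -> "ScanConfig":
        return cls(**{**dict(zoom="low", pixel_size_um=1.55,
                             min_area_um2=50.0, max_area_um2=1500.0),
                      **overrides})

    @classmethod
    def high_zoom(cls, **overrides) -> "ScanConfig":
        return cls(**{**dict(zoom="high", pixel_size_um=0.155,
                             min_area_um2=0.5, max_area_um2=50.0),
                      **overrides})

    @property
    def min_area_px(self) -> float:
        return self.min_area_um2 / self.pixel_size_um**2

    @property
    def working_channel(self) -> str:
        if self.crop_channel is not None:
            return self.crop_channel
        return "blue" if self.zoom == "low" else "sum"


@dataclass
class TileStack:
    """Ordered set of 8-bit RGB tiles forming a mosaic, plus metadata."""

    tiles: list[np.ndarray]
    positions: list[tuple[int, int]]
    metadata: dict = field(default_factory=dict)
    scan: ScanConfig = field(default_factory=ScanConfig)

    def __post_init__(self) -> None:
        if len(self.tiles) != len(self.positions):
            raise ValueError("tiles and positions must have equal length")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("grid positions must be unique")
        shapes = {t.shape for t in self.tiles}
        if len(shapes) > 1:
            raise ValueError(f"tiles must share dimensions, got {shapes}")
        for t in self.tiles:
            if t.dtype != np.uint8 or t.ndim != 3 or t.shape[2] != 3:
                raise ValueError("tiles must be 8-bit RGB (H, W, 3) uint8")

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self.tiles[0].shape[:2]

    @property
    def grid_shape(self) -> tuple[int, int]:
        rows = max(p[0] for p in self.positions) + 1
        cols = max(p[1] for p in self.positions) + 1
        return rows, cols

    def subset(self, indices: Sequence[int]) -> "TileStack":
        return TileStack(
            tiles=[self.tiles[i] for i in indices],
            positions=[self.positions[i] for i in indices],
            metadata=dict(self.metadata),
            scan=self.scan,
        )


@dataclass
class ParticleRecord:
    """One detected particle with its provenance and measurements."""

    id: int
    holder: str
    lamella: str
    coating: str
    zoom: str
    x_um: float
    y_um: float
    area_um2: float
    elongation: float
    bbox_um: tuple[float, float, float, float]
    touches_border: bool
    has_halo: bool = False


def _blue(tile: np.ndarray) -> np.ndarray:
    return tile[..., 2]


def _working_image(tile: np.ndarray, scan: ScanConfig) -> np.ndarray:
    """Channel used for local refinement, as float in [0, 255]."""
    if scan.working_channel == "blue":
        return _blue(tile).astype(np.float64)
    # 8-bit rescale of the per-pixel R+G+B sum (range 0-765 -> 0-255)
    return tile.sum(axis=2, dtype=np.float64) / 3.0


def reject_frames(
    stack: TileStack, k: float | None = None
) -> tuple[TileStack, list[int]]:
    """Remove tiles whose blue-channel mean deviates from the stack median.

    A tile is rejected when ``|mean_i - median(means)| > k * sbar`` where
    ``sbar`` is the average over tiles of the per-tile standard deviation.
    Macroscopic occluders darken a tile's mean well past this band; the
    test is two-sided so anomalously bright frames (glare, missing tile)
    are caught as well. Statistics are computed once from the full stack.

    Returns the kept stack and the list of rejected tile indices.
    """
    if len(stack) == 0:
        raise ValueError("cannot reject frames of an empty stack")
    if k is None:
        k = stack.scan.rejection_k
    means = np.array([_blue(t).mean() for t in stack.tiles])
    stds = np.array([_blue(t).std() for t in stack.tiles])
    median = np.median(means)
    sbar = stds.mean()
    rejected = [i for i in range(len(stack)) if abs(means[i] - median) > k * sbar]
    kept = stack.subset([i for i in range(len(stack)) if i not in set(rejected)])
    return kept, rejected


def segment_global(tile: np.ndarray, scan: ScanConfig) -> np.ndarray:
    """Global segmentation: blue channel strictly below the threshold.

    Connected components are labelled with 8-connectivity; components
    smaller than the zoom's minimum particle area are discarded. Returns a
    consecutively relabelled integer mask (0 = background).
    """
    if tile.dtype != np.uint8 or tile.ndim != 3:
        raise ValueError("expected an 8-bit RGB tile")
    mask = _blue(tile) < scan.global_threshold
    labels = skmeasure.label(mask, connectivity=2)
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= scan.min_area_px)
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=labels.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def refine_crop(
    tile: np.ndarray,
    bbox: tuple[int, int, int, int],
    scan: ScanConfig,
) -> np.ndarray:
    """Refine one candidate with a local threshold.

    The crop is the candidate bounding box ``(min_row, min_col, max_row,
    max_col)`` (exclusive stops) padded by ``crop_margin_px`` and clipped
    to the tile. The local threshold is ``local_alpha * mean(crop)`` of
    the working channel; the refined mask keeps only the connected
    component(s) overlapping the original candidate box. Returns a
    full-tile boolean mask (all False when the candidate dissolves, which
    the caller treats as a dropped candidate, not an error).
    """
    h, w = tile.shape[:2]
    r0, c0, r1, c1 = bbox
    m = scan.crop_margin_px
    pr0, pc0 = max(r0 - m, 0), max(c0 - m, 0)
    pr1, pc1 = min(r1 + m, h), min(c1 + m, w)
    work = _working_image(tile, scan)[pr0:pr1, pc0:pc1]
    thresh = scan.local_alpha * work.mean()
    local = work < thresh
    out = np.zeros((h, w), dtype=bool)
    if not local.any():
        return out
    labels = skmeasure.label(local, connectivity=2)
    cand = labels[(r0 - pr0):(r1 - pr0), (c0 - pc0):(c1 - pc0)]
    hit = np.unique(cand[cand > 0])
    if hit.size == 0:
        return out
    out[pr0:pr1, pc0:pc1] = np.isin(labels, hit)
    return out


def _moments(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    """Centroid-free second-moment summary: (var_r, var_c, cov_rc).

    Each pixel is treated as a unit square, contributing 1/12 to the
    diagonal; a one-pixel-wide line then has a finite minor axis.
    """
    vr = rows.var() + 1.0 / 12.0
    vc = cols.var() + 1.0 / 12.0
    cv = ((rows - rows.mean()) * (cols - cols.mean())).mean()
    return vr, vc, cv


def _elongation(rows: np.ndarray, cols: np.ndarray) -> float:
    vr, vc, cv = _moments(rows, cols)
    common = 0.5 * (vr + vc)
    diff = 0.5 * np.hypot(vr - vc, 2 * cv)
    lam1, lam2 = common + diff, common - diff
    return float(np.sqrt(lam1 / lam2))


def _measure_pixels(
    rows: np.ndarray,
    cols: np.ndarray,
    scan: ScanConfig,
    touches_border: bool,
) -> dict:
    px = scan.pixel_size_um
    area = rows.size * px**2
    x = (cols.mean() + 0.5) * px
    y = (rows.mean() + 0.5) * px
    bbox = (cols.min() * px, rows.min() * px,
            (cols.max() + 1) * px, (rows.max() + 1) * px)
    return dict(
        x_um=float(x),
        y_um=float(y),
        area_um2=float(area),
        elongation=_elongation(rows.astype(float), cols.astype(float)),
        bbox_um=tuple(float(v) for v in bbox),
        touches_border=bool(touches_border),
    )


def measure(
    mask: np.ndarray,
    scan: ScanConfig,
    offset_px: tuple[int, int] = (0, 0),
) -> dict:
    """Measure a single-component mask.

    Returns area (um^2), mosaic-frame centroid and bounding box (um),
    equivalent-ellipse elongation, and a border-contact flag. ``offset_px``
    is the (row, col) position of the tile's origin in the mosaic.
    """
    if mask.sum() == 0:
        raise ValueError("cannot measure an empty mask")
    n_comp = skmeasure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"mask must contain exactly one component, got {n_comp}")
    rows, cols = np.nonzero(mask)
    touches = bool(
        rows.min() == 0 or cols.min() == 0
        or rows.max() == mask.shape[0] - 1 or cols.max() == mask.shape[1] - 1
    )
    return _measure_pixels(
        rows + offset_px[0], cols + offset_px[1], scan, touches
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def run_detection(
    stack: TileStack, return_pixels: bool = False
):
    """Run the full detection chain on a tile stack.

    High-zoom stacks are first cleaned by :func:`reject_frames` (low-zoom
    acquisition is not subject to macroscopic shadowing at the same rate
    and is segmented in full). Each kept tile is segmented globally, each
    candidate refined locally and measured; particles split across
    adjacent tiles are merged when their bounding boxes touch within one
    pixel in mosaic coordinates. Refined particles below the zoom's
    minimum area are dropped.

    Returns a :class:`pandas.DataFrame` with one row per particle
    (columns ``id, holder, lamella, coating, zoom, x_um, y_um, area_um2,
    elongation, touches_border, has_halo`` plus bounding-box and tile
    bookkeeping columns). With ``return_pixels=True`` also returns the
    list of (rows, cols) mosaic pixel-index arrays, aligned with the rows.
    """
    import pandas as pd

    scan = stack.scan
    meta = stack.metadata
    rejected: list[int] = []
    if scan.zoom == "high":
        stack, rejected = reject_frames(stack)
        if rejected:
            logger.info("rejected %d tile(s): %s", len(rejected), rejected)

    th, tw = stack.tile_shape
    order = sorted(range(len(stack)), key=lambda i: stack.positions[i])

    # candidate = (mosaic rows, mosaic cols, touches_tile_border)
    candidates: list[tuple[np.ndarray, np.ndarray, bool]] = []
    for i in order:
        tile = stack.tiles[i]
        grow, gcol = stack.positions[i]
        off_r, off_c = grow * th, gcol * tw
        labels = segment_global(tile, scan)
        refined_union = np.zeros((th, tw), dtype=bool)
        for region in skmeasure.regionprops(labels):
            refined = refine_crop(tile, region.bbox, scan)
            if not refined.any():
                logger.debug("candidate at %s dropped: empty refined mask",
                             region.bbox)
                continue
            refined_union |= refined
        # nearby candidates may refine to the same pixels; extracting
        # components from the per-tile union deduplicates them
        for sub in skmeasure.regionprops(
            skmeasure.label(refined_union, connectivity=2)
        ):
            rows, cols = sub.coords[:, 0], sub.coords[:, 1]
            touches = bool(
                rows.min() == 0 or cols.min() == 0
                or rows.max() == th - 1 or cols.max() == tw - 1
            )
            if not touches and sub.num_pixels < scan.min_area_px:
                continue  # border pieces survive until after merging
            candidates.append((rows + off_r, cols + off_c, touches))

    # merge split particles: border-touching candidates whose mosaic
    # bounding boxes meet within 1 px
    uf = _UnionFind(len(candidates))
    border_idx = [i for i, c in enumerate(candidates) if c[2]]
    boxes = {
        i: (
            candidates[i][0].min(), candidates[i][1].min(),
            candidates[i][0].max(), candidates[i][1].max(),
        )
        for i in border_idx
    }
    for a_pos, a in enumerate(border_idx):
        ra0, ca0, ra1, ca1 = boxes[a]
        for b in border_idx[a_pos + 1:]:
            rb0, cb0, rb1, cb1 = boxes[b]
            if ra0 <= rb1 + 1 and rb0 <= ra1 + 1 \
                    and ca0 <= cb1 + 1 and cb0 <= ca1 + 1:
                uf.union(a, b)

    groups: dict[int, list[int]] = {}
    for i in range(len(candidates)):
        groups.setdefault(uf.find(i), []).append(i)

    records: list[dict] = []
    pixel_sets: list[tuple[np.ndarray, np.ndarray]] = []
    for members in groups.values():
        rows = np.concatenate([candidates[i][0] for i in members])
        cols = np.concatenate([candidates[i][1] for i in members])
        if rows.size < scan.min_area_px:
            continue
        touches = any(candidates[i][2] for i in members)
        rec = _measure_pixels(rows, cols, scan, touches)
        records.append(rec)
        pixel_sets.append((rows, cols))

    sort_key = sorted(
        range(len(records)),
        key=lambda i: (records[i]["y_um"], records[i]["x_um"]),
    )
    records = [records[i] for i in sort_key]
    pixel_sets = [pixel_sets[i] for i in sort_key]

    table = pd.DataFrame(
        [
            dict(
                id=i,
                holder=meta.get("holder", ""),
                lamella=meta.get("lamella", ""),
                coating=meta.get("coating", ""),
                zoom=scan.zoom,
                x_um=r["x_um"],
                y_um=r["y_um"],
                area_um2=r["area_um2"],
                elongation=r["elongation"],
                touches_border=r["touches_border"],
                has_halo=False,
                bbox_x0_um=r["bbox_um"][0],
                bbox_y0_um=r["bbox_um"][1],
                bbox_x1_um=r["bbox_um"][2],
                bbox_y1_um=r["bbox_um"][3],
            )
            for i, r in enumerate(records)
        ],
        columns=[
            "id", "holder", "lamella", "coating", "zoom", "x_um", "y_um",
            "area_um2", "elongation", "touches_border", "has_halo",
            "bbox_x0_um", "bbox_y0_um", "bbox_x1_um", "bbox_y1_um",
        ],
    )
    table.attrs["rejected_tiles"] = rejected
    if return_pixels:
        return table, pixel_sets
    return table
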