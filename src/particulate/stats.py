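"""Contamination statistics for particle tables.

Implements the quantities reported in surface-contamination surveys:
particle densities with tile-to-tile dispersion, coating x holder density
grids with marginal means, cumulative particle size functions (CSFs),
unpaired Student t-tests between coatings, linear coverage extrapolation
over multi-decade horizons, and the log-decade Surface Cleanliness by
Particle concentration (SCP) class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from particulate.scenes import SizeLaw, truncated_lognormal_mean

__all__ = [
    "DensitySummary",
    "CumulativeSizeFunction",
    "CoverageForecast",
    "density",
    "summary_grid",
    "cumulative_size_function",
    "histogram_mode",
    "t_test_unpaired",
    "compare_coatings",
    "extrapolate_coverage",
    "cleanliness_class",
]


@dataclass
class DensitySummary:
    """Coating x holder grid of densities with marginal means.

    ``cells`` maps ``(coating, holder)`` to ``(d, sd, n_particles,
    scanned_area_mm2)``; the marginals are arithmetic means and sample
    (n-1) standard deviations over each row/column of d values.
    """

    cells: dict[tuple[str, str], tuple[float, float, int, float]]
    row_means: dict[str, tuple[float, float]]
    col_means: dict[str, tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        coatings = sorted({c for c, _ in self.cells})
        holders = sorted({h for _, h in self.cells})
        data = {h: [self.cells[(c, h)][0] for c in coatings] for h in holders}
        frame = pd.DataFrame(data, index=coatings)
        frame["<d>"] = [self.row_means[c][0] for c in coatings]
        col_row = [self.col_means[h][0] for h in holders] + [float("nan")]
        frame.loc["<d>"] = col_row
        return frame


@dataclass
class CumulativeSizeFunction:
    """Binned cumulative fraction of particle areas for one group."""

    bin_edges: np.ndarray
    cum_fraction: np.ndarray
    coating: str = ""
    holder: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cum_fraction = np.asarray(self.cum_fraction, dtype=float)


@dataclass
class CoverageForecast:
    """Linear extrapolation of fractional surface coverage."""

    horizon_periods: float
    coverage_percent: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)


def density(
    table: pd.DataFrame | int,
    scanned_area_mm2: float,
    tile_partition: Sequence[tuple[float, float, float, float]] | None = None,
) -> tuple[float, float]:
    """Particle density (per mm^2) and its dispersion.

    ``table`` is a particle table (or a bare count). The density is
    ``d = N / scanned_area_mm2``. When ``tile_partition`` is given — a
    sequence of ``(x0_um, y0_um, x1_um, y1_um)`` rectangles covering the
    scanned area — the dispersion is the sample standard deviation of the
    per-tile densities scaled to the lamella level, ``sd(d_tiles) /
    sqrt(n_tiles)``; without a partition the dispersion is NaN (the
    particle table alone carries no replication).
    """
    if scanned_area_mm2 <= 0:
        raise ValueError("scanned area must be positive")
    if isinstance(table, (int, np.integer)):
        n = int(table)
        xs = ys = None
    else:
        n = len(table)
        xs = table["x_um"].to_numpy() if n else np.empty(0)
        ys = table["y_um"].to_numpy() if n else np.empty(0)
    d = n / scanned_area_mm2
    if n == 0:
        return 0.0, 0.0
    if tile_partition is None:
        return d, float("nan")
    per_tile = []
    for x0, y0, x1, y1 in tile_partition:
        if xs is None:
            raise ValueError("tile_partition requires a full particle table")
        a_mm2 = (x1 - x0) * (y1 - y0) * 1e-6
        inside = ((xs >= x0) & (xs < x1) & (ys >= y0) & (ys < y1)).sum()
        per_tile.append(inside / a_mm2)
    per_tile = np.asarray(per_tile)
    if per_tile.size < 2:
        return d, 0.0
    sd = per_tile.std(ddof=1) / math.sqrt(per_tile.size)
    return d, float(sd)


def summary_grid(
    cells: Mapping[tuple[str, str], float | tuple],
) -> DensitySummary:
    """Build a density summary grid with row and column marginals.

    ``cells`` maps ``(coating, holder)`` to a density (or a tuple whose
    first element is the density; optional further elements are sd,
    particle count and scanned area). The grid must be complete: every
    coating must have a value for every holder.
    """
    norm_cells: dict[tuple[str, str], tuple[float, float, int, float]] = {}
    for key, val in cells.items():
        if isinstance(val, (int, float, np.floating)):
            norm_cells[key] = (float(val), float("nan"), 0, float("nan"))
        else:
            v = tuple(val) + (float("nan"),) * (4 - len(val))
            norm_cells[key] = (float(v[0]), float(v[1]), v[2], v[3])
    coatings = sorted({c for c, _ in norm_cells})
    holders = sorted({h for _, h in norm_cells})
    for c in coatings:
        for h in holders:
            if (c, h) not in norm_cells:
                raise ValueError(f"missing grid cell ({c!r}, {h!r})")

    def _marginal(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values)
        sd = arr.std(ddof=1) if arr.size > 1 else 0.0
        return float(arr.mean()), float(sd)

    row_means = {
        c: _marginal([norm_cells[(c, h)][0] for h in holders])
        for c in coatings
    }
    col_means = {
        h: _marginal([norm_cells[(c, h)][0] for c in coatings])
        for h in holders
    }
    return DensitySummary(cells=norm_cells, row_means=row_means,
                          col_means=col_means)


def cumulative_size_function(
    areas: Sequence[float],
    class_range: tuple[float, float],
    n_bins: int = 30,
    coating: str = "",
    holder: str = "",
) -> CumulativeSizeFunction:
    """Cumulative particle size function over log-spaced area bins.

    ``cum_fraction[i]`` is the percentage of particles with area at or
    below ``bin_edges[i]``. Edges span the class range geometrically; the
    final edge is the range upper bound, so the function ends at 100%
    whenever all areas lie inside the range.
    """
    areas = np.asarray(list(areas), dtype=float)
    if areas.size == 0:
        raise ValueError("cannot build a size function from no particles")
    lo, hi = class_range
    if not 0 < lo < hi:
        raise ValueError("class range must satisfy 0 < lower < upper")
    if n_bins < 2:
        raise ValueError("need at least two bins")
    if areas.min() < lo or areas.max() > hi:
        raise ValueError("all areas must lie inside the class range")
    edges = np.geomspace(lo, hi, n_bins)
    cum = 100.0 * np.searchsorted(np.sort(areas), edges, side="right") \
        / areas.size
    return CumulativeSizeFunction(bin_edges=edges, cum_fraction=cum,
                                  coating=coating, holder=holder)


def histogram_mode(
    areas: Sequence[float],
    bin_width: float = 50.0,
    start: float = 50.0,
) -> float:
    """Most probable size: centre of the tallest fixed-width histogram bin.

    Defaults (50 um^2 bins from the coarse lower bound) match the
    low-zoom size-distribution histograms.
    """
    areas = np.asarray(list(areas), dtype=float)
    if areas.size == 0:
        raise ValueError("cannot locate the mode of no particles")
    n_bins = int(math.ceil((areas.max() - start) / bin_width)) + 1
    edges = start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(areas, bins=edges)
    i = int(np.argmax(counts))
    return float(edges[i] + bin_width / 2)


def t_test_unpaired(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, int, float]:
    """Pooled-variance unpaired Student t-test, two-sided.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2``. Degenerate inputs
    with zero pooled variance give ``(0, df, 1)`` when the means are
    equal and ``p = 0`` (with a warning) when they differ.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with unequal means; p = 0",
                      RuntimeWarning, stacklevel=2)
        return math.copysign(math.inf, a.mean() - b.mean()), df, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def compare_coatings(
    csfs: Mapping[str, Mapping[str, CumulativeSizeFunction]],
    area_range: tuple[float, float],
) -> dict[tuple[str, str], dict[str, float]]:
    """Pairwise coating comparison of cumulative size functions.

    ``csfs[coating][holder]`` holds one CSF per holder. For each coating
    pair the per-holder cumulative fractions at the bin edges inside
    ``area_range`` are pooled into one sample per coating and compared
    with :func:`t_test_unpaired`. Returns ``{(coating_a, coating_b):
    {"t": ..., "df": ..., "p": ...}}`` with coatings in sorted order.
    """
    lo, hi = area_range
    if not lo < hi:
        raise ValueError("empty area range")
    samples: dict[str, np.ndarray] = {}
    for coating, by_holder in csfs.items():
        if len(by_holder) < 2:
            raise ValueError(
                f"coating {coating!r} needs at least two holders"
            )
        vals = []
        for csf in by_holder.values():
            sel = (csf.bin_edges >= lo) & (csf.bin_edges <= hi)
            if not sel.any():
                raise ValueError(
                    f"no bin edges inside {area_range} for {coating!r}"
                )
            vals.append(csf.cum_fraction[sel])
        samples[coating] = np.concatenate(vals)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for a, b in combinations(sorted(samples), 2):
        t, df, p = t_test_unpaired(samples[a], samples[b])
        out[(a, b)] = {"t": t, "df": float(df), "p": p}
    return out


def extrapolate_coverage(
    class_params: Mapping[str, tuple[float, SizeLaw | tuple]],
    horizon_periods: float,
) -> CoverageForecast:
    """Linear coverage extrapolation over exposure periods.

    ``class_params`` maps a size-class label to ``(density_per_mm2,
    size_law)`` where the law is a :class:`~particulate.scenes.SizeLaw`
    or a ``(mode, sigma_log, lower, upper)`` tuple. One exposure period
    deposits ``density * E[area]`` um^2 of particle area per mm^2 of
    surface; the fractional coverage is

    ``coverage% = 100 * horizon * sum_class density * E[area] * 1e-6``

    with ``E[area]`` the truncated log-normal mean. Strictly linear in
    the horizon (no saturation or overlap correction).
    """
    if horizon_periods < 0:
        raise ValueError("horizon must be non-negative")
    per_class: dict[str, dict[str, float]] = {}
    rate = 0.0
    for label, (dens, law) in class_params.items():
        if dens < 0:
            raise ValueError(f"negative density for class {label!r}")
        if not isinstance(law, SizeLaw):
            law = SizeLaw(*law)
        e_area = law.mean()
        rate += dens * e_area * 1e-6
        per_class[label] = {
            "density_per_mm2": float(dens),
            "expected_area_um2": float(e_area),
        }
    coverage = 100.0 * horizon_periods * rate
    return CoverageForecast(
        horizon_periods=float(horizon_periods),
        coverage_percent=float(coverage),
        per_class=per_class,
    )


def cleanliness_class(density_per_m2: float) -> int:
    """Surface Cleanliness by Particle concentration class (log-decade).

    ``density_per_m2`` is the areal concentration of particles with
    equivalent diameter >= 1 um, per square metre. The class is the
    smallest integer N with density <= 10^N (so 10^6 per m^2 is class 6);
    concentrations at or below 1 per m^2 report class 0.
    """
    if density_per_m2 < 0:
        raise ValueError("density must be non-negative")
    if density_per_m2 <= 1.0:
        return 0
    # round in log space so exact powers of ten stay in their decade
    return max(int(math.ceil(round(math.log10(density_per_m2), 12))), 0)
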