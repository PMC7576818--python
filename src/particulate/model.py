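"""Model/Results interface over the contamination statistics.

:class:`ContaminationModel` is constructed from a particle table (one row
per detected particle, as produced by
:func:`particulate.detection.run_detection` and annotated by
:func:`particulate.classify.annotate`); :meth:`ContaminationModel.fit`
computes the survey statistics and returns a
:class:`ContaminationResults` carrying density grids, cumulative size
functions, pairwise coating comparisons, a coverage forecast and a
cleanliness class, with a text ``summary()`` and plotting helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from particulate.classify import SIZE_CLASS_BOUNDS, size_class
from particulate.scenes import SizeLaw, _DEFAULT_SIZE_LAWS
from particulate.stats import (
    CoverageForecast,
    CumulativeSizeFunction,
    DensitySummary,
    cleanliness_class,
    compare_coatings,
    cumulative_size_function,
    histogram_mode,
    summary_grid,
)

__all__ = ["ContaminationModel", "ContaminationResults"]

#: area of a 1 um equivalent-diameter disk; particles at or above it
#: count toward the cleanliness class
_MIN_SCP_AREA_UM2 = math.pi / 4


class ContaminationModel:
    """Surface-contamination survey model for a particle table.

    Parameters
    ----------
    table : pandas.DataFrame
        Particle table with at least ``coating, holder, zoom, area_um2``
        columns (``size_class`` is derived if absent).
    scanned_area_mm2 : float or mapping
        Scanned area per lamella. Either one value used for every
        (coating, holder) cell, or a mapping ``(coating, holder) -> mm^2``.
        Separate areas per zoom can be given by mapping
        ``(coating, holder, zoom)``.
    size_laws : mapping, optional
        ``class label -> SizeLaw`` used by the coverage forecast;
        defaults to the calibrated survey laws (coarse mode 155 um^2,
        sigma 0.7; fine mode 2 um^2, sigma 1.0).
    period_months : float
        Duration of one exposure period (default 6 months).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        scanned_area_mm2,
        size_laws: Mapping[str, SizeLaw] | None = None,
        period_months: float = 6.0,
    ) -> None:
        table = table.copy()
        required = {"coating", "holder", "area_um2"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"particle table lacks columns {sorted(missing)}")
        if "size_class" not in table.columns:
            table["size_class"] = [size_class(a) for a in table["area_um2"]]
        self.table = table
        self.scanned_area_mm2 = scanned_area_mm2
        self.size_laws = dict(size_laws or _DEFAULT_SIZE_LAWS)
        self.period_months = period_months

    @classmethod
    def from_csv(cls, path, scanned_area_mm2, **kwargs) -> "ContaminationModel":
        from particulate.io import read_particle_table

        return cls(read_particle_table(path), scanned_area_mm2, **kwargs)

    # -- helpers -----------------------------------------------------------

    def _cell_area(self, coating: str, holder: str, zoom: str | None) -> float:
        area = self.scanned_area_mm2
        if isinstance(area, Mapping):
            for key in ((coating, holder, zoom), (coating, holder)):
                if key in area:
                    return float(area[key])
            raise KeyError(f"no scanned area for cell ({coating}, {holder})")
        return float(area)

    def _class_table(self, label: str) -> pd.DataFrame:
        return self.table[self.table["size_class"] == label]

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        n_bins: int = 30,
        horizon_periods: float = 40.0,
        compare_ranges: Mapping[str, tuple[float, float]] | None = None,
    ) -> "ContaminationResults":
        """Compute the survey statistics.

        ``horizon_periods`` sets the coverage-forecast horizon (40
        six-month periods = 20 years). ``compare_ranges`` maps a size
        class to the area window over which coatings are compared
        (defaults: 200-900 um^2 for coarse, 0.5-10 um^2 for fine — the
        windows where coating effects concentrate).
        """
        compare_ranges = dict(compare_ranges
                              or {"coarse": (200.0, 900.0),
                                  "fine": (0.5, 10.0)})
        coatings = sorted(self.table["coating"].unique())
        holders = sorted(self.table["holder"].unique())

        grids: dict[str, DensitySummary] = {}
        csfs: dict[str, dict[str, dict[str, CumulativeSizeFunction]]] = {}
        comparisons: dict[str, dict[tuple[str, str], dict[str, float]]] = {}
        modes: dict[str, float] = {}
        mean_density: dict[str, float] = {}

        zoom_of = {"fine": "high", "coarse": "low", "macroscopic": "low"}
        for label in ("coarse", "fine", "macroscopic"):
            sub = self._class_table(label)
            if sub.empty:
                continue
            cells = {}
            complete = True
            for c in coatings:
                for h in holders:
                    n = len(sub[(sub["coating"] == c) & (sub["holder"] == h)])
                    try:
                        a = self._cell_area(c, h, zoom_of[label])
                    except KeyError:
                        complete = False
                        continue
                    cells[(c, h)] = (n / a, float("nan"), n, a)
            if complete and cells:
                grids[label] = summary_grid(cells)
                mean_density[label] = float(
                    np.mean([v[0] for v in grids[label].cells.values()])
                )
            lo, hi = SIZE_CLASS_BOUNDS[label]
            hi = min(hi, float(sub["area_um2"].max()) + 1.0)
            by_coating: dict[str, dict[str, CumulativeSizeFunction]] = {}
            for c in coatings:
                by_holder = {}
                for h in holders:
                    areas = sub[(sub["coating"] == c)
                                & (sub["holder"] == h)]["area_um2"]
                    if len(areas) == 0:
                        continue
                    by_holder[h] = cumulative_size_function(
                        areas, (lo, hi), n_bins=n_bins, coating=c, holder=h
                    )
                if by_holder:
                    by_coating[c] = by_holder
            csfs[label] = by_coating
            if label in compare_ranges and len(by_coating) >= 2 and all(
                len(v) >= 2 for v in by_coating.values()
            ):
                comparisons[label] = compare_coatings(
                    by_coating, compare_ranges[label]
                )
            if label == "coarse":
                modes[label] = histogram_mode(sub["area_um2"])

        forecast = None
        forecast_classes = {
            label: (mean_density[label], self.size_laws[label])
            for label in mean_density
            if label in self.size_laws
        }
        if forecast_classes:
            from particulate.stats import extrapolate_coverage

            forecast = extrapolate_coverage(forecast_classes, horizon_periods)

        # cleanliness: particles with equivalent diameter >= 1 um per m^2
        big = self.table[self.table["area_um2"] >= _MIN_SCP_AREA_UM2]
        total_area = 0.0
        for c in coatings:
            for h in holders:
                for zoom in set(zoom_of.values()):
                    try:
                        total_area += self._cell_area(c, h, zoom)
                        break
                    except KeyError:
                        continue
        scp = None
        if total_area > 0:
            scp = cleanliness_class(len(big) / total_area * 1e6)

        return ContaminationResults(
            model=self,
            density_grids=grids,
            mean_density=mean_density,
            csfs=csfs,
            comparisons=comparisons,
            histogram_modes=modes,
            forecast=forecast,
            cleanliness=scp,
        )


@dataclass
class ContaminationResults:
    """Fitted survey statistics with reporting helpers."""

    model: ContaminationModel
    density_grids: dict[str, DensitySummary]
    mean_density: dict[str, float]
    csfs: dict[str, dict[str, dict[str, CumulativeSizeFunction]]]
    comparisons: dict[str, dict[tuple[str, str], dict[str, float]]]
    histogram_modes: dict[str, float]
    forecast: CoverageForecast | None
    cleanliness: int | None

    def class_counts(self) -> dict[str, int]:
        return self.model.table["size_class"].value_counts().to_dict()

    def summary(self) -> str:
        lines = ["Surface contamination survey", "=" * 28, ""]
        counts = self.class_counts()
        total = sum(counts.values())
        lines.append(f"Particles analysed: {total}")
        for label in ("fine", "coarse", "macroscopic"):
            if label in counts:
                lines.append(f"  {label:<12s} {counts[label]}")
        lines.append("")
        for label, grid in self.density_grids.items():
            lines.append(f"{label.capitalize()} particle density "
                         "(per mm^2), coating x holder:")
            lines.append(grid.to_frame().round(2).to_string())
            lines.append("")
        for label, mode in self.histogram_modes.items():
            lines.append(
                f"Most probable {label} size: {mode:.0f} um^2 "
                "(50 um^2 histogram bins)"
            )
        for label, pairs in self.comparisons.items():
            lines.append(f"Coating comparisons, {label} class "
                         "(unpaired t-test):")
            for (a, b), res in pairs.items():
                lines.append(
                    f"  {a} vs {b}: t = {res['t']:+.2f}, "
                    f"df = {int(res['df'])}, p = {res['p']:.3g}"
                )
        if self.forecast is not None:
            years = self.forecast.horizon_periods \
                * self.model.period_months / 12.0
            lines.append("")
            lines.append(
                f"Coverage forecast: {self.forecast.coverage_percent:.2f}% "
                f"after {self.forecast.horizon_periods:.0f} periods "
                f"({years:.0f} years)"
            )
        if self.cleanliness is not None:
            lines.append(
                f"Surface cleanliness class (particles > 1 um): "
                f"{self.cleanliness}"
            )
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_csf(self, label: str = "coarse", ax=None):
        """Plot cumulative size functions per coating (holder-averaged)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for coating, by_holder in self.csfs.get(label, {}).items():
            edges = next(iter(by_holder.values())).bin_edges
            stackd = np.vstack([c.cum_fraction for c in by_holder.values()])
            mean = stackd.mean(axis=0)
            sd = stackd.std(axis=0, ddof=1) if len(by_holder) > 1 else None
            line, = ax.plot(edges, mean, label=coating)
            if sd is not None:
                ax.errorbar(edges, mean, yerr=sd, fmt="none",
                            ecolor=line.get_color(), alpha=0.4)
        ax.set_xscale("log")
        ax.set_xlabel("Area (um^2)")
        ax.set_ylabel("Cumulative fraction (%)")
        ax.set_title(f"Cumulative particle size function ({label})")
        ax.legend()
        return ax

    def plot_size_distribution(self, label: str = "coarse", ax=None,
                               bin_width: float = 50.0):
        """Histogram of particle areas with the cumulative curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.model.table[self.model.table["size_class"] == label]
        areas = sub["area_um2"].to_numpy()
        lo = SIZE_CLASS_BOUNDS[label][0]
        if label == "fine":
            bin_width = 1.0
        edges = np.arange(lo, areas.max() + bin_width, bin_width)
        ax.hist(areas, bins=edges, color="steelblue", alpha=0.8)
        ax.set_xlabel("Area (um^2)")
        ax.set_ylabel("Count")
        ax2 = ax.twinx()
        xs = np.sort(areas)
        ax2.plot(xs, 100.0 * np.arange(1, xs.size + 1) / xs.size,
                 color="firebrick")
        ax2.set_ylabel("Cumulative (%)")
        ax.set_title(f"{label.capitalize()} particle size distribution "
                     f"(n = {areas.size})")
        return ax
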