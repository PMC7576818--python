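"""End-to-end orchestration: simulate -> detect -> classify -> stats.

A run is driven by a single JSON configuration (``//`` comments allowed)
so that one file reproduces one run bit-for-bit: every artifact is
stamped with the configuration hash and the seed, and a rerun with the
same configuration yields identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from particulate import io
from particulate.classify import annotate
from particulate.detection import ScanConfig, run_detection
from particulate.model import ContaminationModel
from particulate.scenes import SceneSpec, SizeLaw, render_tiles, sample_truth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "detect": True, "classify": True, "stats": True})
    scenes: list = field(default_factory=list)
    scan: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    tiles_dirs: list = field(default_factory=list)
    write_tiles: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_COMMENT_RE = re.compile(r"^\s*//.*$", re.MULTILINE)


def load_config(path) -> RunConfig:
    """Load a run configuration from JSON (``//`` comment lines allowed)."""
    text = _COMMENT_RE.sub("", Path(path).read_text())
    return RunConfig(**json.loads(text))


def _build_spec(overrides: dict, seed: int) -> SceneSpec:
    d = dict(overrides)
    if "size_law_per_class" in d:
        d["size_law_per_class"] = {
            k: v if isinstance(v, SizeLaw) else SizeLaw(**v)
            for k, v in d["size_law_per_class"].items()
        }
    d.setdefault("seed", seed)
    return SceneSpec(**d)


def _scan_for(zoom: str, overrides: dict) -> ScanConfig:
    base = ScanConfig.low_zoom if zoom == "low" else ScanConfig.high_zoom
    ov = dict(overrides)
    ov.pop("zoom", None)
    if "tile_shape_px" in ov:
        ov["tile_shape_px"] = tuple(ov["tile_shape_px"])
    return base(**ov)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the enabled stages and write a run directory.

    Artifacts: ``config.json`` (resolved configuration + hash),
    ``particles.csv`` (classified particle table), ``truth_*.csv`` per
    simulated scene, ``density_summary_*.csv``, ``csf.csv``,
    ``comparisons.json``, ``forecast.json``, ``report.md`` and figures.
    Any stage failure propagates with the stage name in the log.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"seed={config.seed} config={config.config_hash}"
    (out / "config.json").write_text(json.dumps(
        {"hash": config.config_hash, **config.to_dict()},
        indent=2, sort_keys=True))

    stacks = []
    scene_areas: dict[tuple[str, str, str], float] = {}
    if config.stages.get("simulate", True):
        logger.info("stage: simulate (%d scene(s))", len(config.scenes))
        for i, scene_cfg in enumerate(config.scenes):
            zoom = scene_cfg.get("zoom", "low")
            spec = _build_spec(scene_cfg.get("scene", {}),
                               seed=config.seed * 1009 + i)
            truth = sample_truth(spec)
            scan = _scan_for(zoom, config.scan)
            meta = {k: scene_cfg.get(k, "") for k in
                    ("holder", "lamella", "coating")}
            stack = render_tiles(truth, scan, metadata=meta)
            stacks.append(stack)
            key = (meta["coating"], meta["holder"], zoom)
            scene_areas[key] = scene_areas.get(key, 0.0) + spec.area_mm2
            name = f"{meta['coating']}_{meta['holder']}_{meta['lamella']}_{zoom}"
            io.write_truth(truth, out / f"truth_{name}.csv",
                           header_comment=stamp)
            if config.write_tiles:
                io.write_tiles(stack, out / "tiles" / name, scene=name)
    elif config.tiles_dirs:
        logger.info("stage: load tiles (%d dir(s))", len(config.tiles_dirs))
        for d in config.tiles_dirs:
            stacks.append(io.read_tiles(d))

    table = pd.DataFrame(columns=io.PARTICLE_COLUMNS)
    if config.stages.get("detect", True) and stacks:
        logger.info("stage: detect")
        parts = []
        rejected_report = {}
        for i, stack in enumerate(stacks):
            t = run_detection(stack)
            if config.stages.get("classify", True):
                t = annotate(t, stack,
                             **{k: v for k, v in config.stats.items()
                                if k in ("elongation_cut",)})
            name = "_".join(str(stack.metadata.get(k, "")) for k in
                            ("coating", "holder", "lamella")) or str(i)
            rejected_report[name] = t.attrs.get("rejected_tiles", [])
            parts.append(t)
        if parts:
            table = pd.concat(parts, ignore_index=True)
            table["id"] = np.arange(len(table))
        (out / "rejected_frames.json").write_text(
            json.dumps({"stamp": stamp, "rejected": rejected_report},
                       indent=2, sort_keys=True))
        io.write_particle_table(table, out / "particles.csv",
                                header_comment=stamp)

    if config.stages.get("stats", True):
        logger.info("stage: stats")
        _write_stats(table, scene_areas, config, out, stamp)

    return out


def _write_stats(table, scene_areas, config, out, stamp) -> None:
    report = ["# Contamination survey report", "", f"`{stamp}`", ""]
    if len(table) == 0:
        report += ["No particles detected: zero counts in every size "
                   "class; densities are zero everywhere."]
        (out / "report.md").write_text("\n".join(report) + "\n")
        return

    if scene_areas:
        area_map = {}
        for (coating, holder, zoom), a in scene_areas.items():
            area_map[(coating, holder, zoom)] = a
        scanned = area_map
    else:
        scanned = float(config.stats.get("scanned_area_mm2", 1.0))

    model = ContaminationModel(table, scanned)
    res = model.fit(
        n_bins=int(config.stats.get("n_bins", 30)),
        horizon_periods=float(config.stats.get("horizon_periods", 40)),
    )

    for label, grid in res.density_grids.items():
        frame = grid.to_frame()
        with open(out / f"density_summary_{label}.csv", "w") as fh:
            fh.write(f"# {stamp}\n")
            frame.to_csv(fh)

    csf_rows = []
    for label, by_coating in res.csfs.items():
        for coating, by_holder in by_coating.items():
            for holder, csf in by_holder.items():
                for edge, frac in zip(csf.bin_edges, csf.cum_fraction):
                    csf_rows.append(dict(size_class=label, coating=coating,
                                         holder=holder, area_um2=edge,
                                         cum_percent=frac))
    if csf_rows:
        with open(out / "csf.csv", "w") as fh:
            fh.write(f"# {stamp}\n")
            pd.DataFrame(csf_rows).to_csv(fh, index=False)

    comparisons = {
        label: {f"{a}|{b}": res_ab for (a, b), res_ab in pairs.items()}
        for label, pairs in res.comparisons.items()
    }
    (out / "comparisons.json").write_text(json.dumps(
        {"stamp": stamp, "comparisons": comparisons}, indent=2,
        sort_keys=True))

    if res.forecast is not None:
        (out / "forecast.json").write_text(json.dumps(
            {"stamp": stamp,
             "horizon_periods": res.forecast.horizon_periods,
             "coverage_percent": res.forecast.coverage_percent,
             "per_class": res.forecast.per_class},
            indent=2, sort_keys=True))

    report += [res.summary(), ""]
    (out / "report.md").write_text("\n".join(report) + "\n")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        for label in res.csfs:
            if res.csfs[label]:
                ax = res.plot_csf(label)
                ax.figure.savefig(figdir / f"csf_{label}.png", dpi=100)
                plt.close(ax.figure)
        for label in ("coarse", "fine"):
            if (table["size_class"] == label).any():
                ax = res.plot_size_distribution(label)
                ax.figure.savefig(figdir / f"sizes_{label}.png", dpi=100)
                plt.close(ax.figure)
    except Exception:  # plotting must never abort a run
        logger.exception("figure generation failed")
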