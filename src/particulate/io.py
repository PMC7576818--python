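"""Reading and writing of tiles, particle tables and scene files.

Tiles are 8-bit RGB TIFFs, one per tile, named ``{scene}_{row}_{col}.tif``
with a JSON metadata sidecar (``metadata.json``) holding the stack
metadata and scan configuration. Particle tables and scene truths are
plain CSV; scene specifications are JSON.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from particulate.detection import ScanConfig, TileStack
from particulate.scenes import SceneSpec, SceneTruth, SizeLaw

__all__ = [
    "write_tiles",
    "read_tiles",
    "write_particle_table",
    "read_particle_table",
    "write_truth",
    "read_truth",
    "write_scene_spec",
    "read_scene_spec",
]

PARTICLE_COLUMNS = [
    "id", "holder", "lamella", "coating", "zoom", "x_um", "y_um",
    "area_um2", "elongation", "touches_border", "has_halo",
]

_TILE_RE = re.compile(r"^(?P<scene>.+)_(?P<row>\d+)_(?P<col>\d+)\.(tif|tiff|png)$")


def _scan_to_dict(scan: ScanConfig) -> dict:
    d = dataclasses.asdict(scan)
    d["tile_shape_px"] = list(d["tile_shape_px"])
    return d


def _scan_from_dict(d: dict) -> ScanConfig:
    d = dict(d)
    if "tile_shape_px" in d:
        d["tile_shape_px"] = tuple(d["tile_shape_px"])
    return ScanConfig(**d)


def write_tiles(stack: TileStack, directory, scene: str = "scene") -> Path:
    """Write one TIFF per tile plus a ``metadata.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tile, (row, col) in zip(stack.tiles, stack.positions):
        tifffile.imwrite(directory / f"{scene}_{row}_{col}.tif", tile)
    sidecar = {
        "scene": scene,
        "metadata": stack.metadata,
        "scan": _scan_to_dict(stack.scan),
        "positions": [list(p) for p in stack.positions],
    }
    (directory / "metadata.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))
    return directory


def read_tiles(directory) -> TileStack:
    """Read a tile directory written by :func:`write_tiles`.

    A missing sidecar falls back to default metadata and scan settings;
    tile grid positions are always parsed from the file names.
    """
    directory = Path(directory)
    sidecar_path = directory / "metadata.json"
    metadata, scan = {}, ScanConfig()
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        metadata = sidecar.get("metadata", {})
        scan = _scan_from_dict(sidecar.get("scan", {}))
    tiles, positions = [], []
    for path in sorted(directory.iterdir()):
        m = _TILE_RE.match(path.name)
        if not m:
            continue
        if path.suffix.lower() in (".tif", ".tiff"):
            img = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            img = iio.imread(path)
        tiles.append(np.asarray(img, dtype=np.uint8))
        positions.append((int(m["row"]), int(m["col"])))
    if not tiles:
        raise FileNotFoundError(f"no tiles found in {directory}")
    order = sorted(range(len(tiles)), key=lambda i: positions[i])
    return TileStack(
        tiles=[tiles[i] for i in order],
        positions=[positions[i] for i in order],
        metadata=metadata,
        scan=scan,
    )


def write_particle_table(table: pd.DataFrame, path, header_comment=None
                         ) -> Path:
    """Write a particle table CSV (canonical column set first)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in PARTICLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table[cols].to_csv(fh, index=False)
    return path


def read_particle_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_truth(truth: SceneTruth, path, header_comment=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        truth.to_dataframe().rename(columns={"area_um2": "area_um2"}).to_csv(
            fh, index=False,
            columns=["id", "x_um", "y_um", "area_um2", "morphotype",
                     "has_halo"],
        )
    return path


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _spec_to_dict(spec: SceneSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["size_law_per_class"] = {
        k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else dict(v)
        for k, v in spec.size_law_per_class.items()
    }
    return d


def write_scene_spec(spec: SceneSpec, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_spec_to_dict(spec), indent=2, sort_keys=True))
    return path


def read_scene_spec(path) -> SceneSpec:
    d = json.loads(Path(path).read_text())
    if "size_law_per_class" in d:
        d["size_law_per_class"] = {
            k: SizeLaw(**v) for k, v in d["size_law_per_class"].items()
        }
    return SceneSpec(**d)
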