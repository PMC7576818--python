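"""Size classes, morphotype flags and drying-halo detection.

Size classes partition projected areas into *fine* [0.5, 50) um^2,
*coarse* [50, 1500] um^2 and *macroscopic* (1500, inf) um^2. The fine/
coarse boundary is half-open at 50 and the coarse class closed at 1500 so
the conventional "50-1500" count is preserved. Shapes are flagged by
elongation only (fiber vs compact); attributing particles to skin flakes,
textile fibers or microbial cells is interpretive and out of scope.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from particulate.detection import ScanConfig

logger = logging.getLogger(__name__)

__all__ = [
    "SIZE_CLASS_BOUNDS",
    "size_class",
    "morphotype_flag",
    "detect_halo",
    "annotate",
]

#: label -> (lower, upper); fine and coarse half-open at 50, coarse
#: closed at 1500.
SIZE_CLASS_BOUNDS: dict[str, tuple[float, float]] = {
    "fine": (0.5, 50.0),
    "coarse": (50.0, 1500.0),
    "macroscopic": (1500.0, float("inf")),
}

DETECTION_FLOOR_UM2 = 0.5


def size_class(area_um2: float) -> str:
    """Assign one area to its size class.

    Areas below the 0.5 um^2 detection floor are not classifiable and
    raise ``ValueError``.
    """
    if area_um2 < DETECTION_FLOOR_UM2:
        raise ValueError(
            f"area {area_um2} um^2 is below the 0.5 um^2 detection floor"
        )
    if area_um2 < 50.0:
        return "fine"
    if area_um2 <= 1500.0:
        return "coarse"
    return "macroscopic"


def morphotype_flag(record, elongation_cut: float = 5.0) -> str:
    """Flag a particle as ``"fiber"`` or ``"compact"`` by elongation.

    ``record`` may be a :class:`~particulate.detection.ParticleRecord`, a
    mapping/Series with an ``elongation`` entry, or a bare elongation
    value. Particles at or above ``elongation_cut`` are fibers.
    """
    if hasattr(record, "elongation"):
        e = record.elongation
    elif isinstance(record, (int, float, np.floating)):
        e = float(record)
    else:
        e = record["elongation"]
    return "fiber" if e >= elongation_cut else "compact"


def detect_halo(
    tile: np.ndarray,
    record,
    scan: ScanConfig,
    tile_offset_px: tuple[int, int] = (0, 0),
    ring_width_px: int = 5,
    k: float = 2.0,
    scale: str = "sem",
) -> bool:
    """Flag a bright drying halo around one particle.

    The particle mask is re-derived from the tile (blue channel strictly
    below the global threshold, restricted to the record's bounding box);
    the test compares the mean intensity of an annulus extending
    ``ring_width_px`` beyond the particle boundary with the tile
    background mean. With ``scale="sem"`` (default) the comparison
    threshold is ``k`` background standard *errors* of an annulus-sized
    mean — the annulus average of n pixels fluctuates with sd/sqrt(n), so
    this keeps the false-positive rate at the nominal level whatever the
    sensor noise; ``scale="std"`` uses ``k`` raw standard deviations.

    Returns ``False`` (with a logged reason) when the annulus would fall
    outside the tile.
    """
    h, w = tile.shape[:2]
    px = scan.pixel_size_um
    off_r, off_c = tile_offset_px

    if hasattr(record, "bbox_um"):
        x0, y0, x1, y1 = record.bbox_um
    else:
        x0, y0 = record["bbox_x0_um"], record["bbox_y0_um"]
        x1, y1 = record["bbox_x1_um"], record["bbox_y1_um"]
    r0 = int(np.floor(y0 / px)) - off_r
    c0 = int(np.floor(x0 / px)) - off_c
    r1 = int(np.ceil(y1 / px)) - off_r
    c1 = int(np.ceil(x1 / px)) - off_c

    pad = ring_width_px + 2
    if r0 - pad < 0 or c0 - pad < 0 or r1 + pad > h or c1 + pad > w:
        logger.debug("halo annulus for particle at (%s, %s) falls outside "
                     "the tile; flag False", x0, y0)
        return False

    blue = tile[..., 2].astype(np.float64)
    window = np.zeros((h, w), dtype=bool)
    window[max(r0, 0):r1, max(c0, 0):c1] = True
    mask = (blue < scan.global_threshold) & window
    if not mask.any():
        logger.debug("no particle pixels under bbox; flag False")
        return False

    annulus = ndimage.binary_dilation(mask, structure=disk(ring_width_px)) & ~mask
    if not annulus.any():
        return False

    background = blue >= scan.global_threshold
    background &= ~annulus
    bg_mean = blue[background].mean()
    bg_std = blue[background].std()
    ann_mean = blue[annulus].mean()
    spread = bg_std / np.sqrt(annulus.sum()) if scale == "sem" else bg_std
    return bool(ann_mean > bg_mean + k * spread)


def annotate(
    table,
    stack=None,
    elongation_cut: float = 5.0,
    ring_width_px: int = 5,
    halo_k: float = 2.0,
):
    """Add ``size_class`` and ``morphotype`` columns to a particle table.

    When ``stack`` (the source :class:`~particulate.detection.TileStack`)
    is given, the ``has_halo`` flag is recomputed with
    :func:`detect_halo`; otherwise any existing flag is kept. Returns a
    new DataFrame.
    """
    out = table.copy()
    out["size_class"] = [size_class(a) for a in out["area_um2"]]
    out["morphotype"] = [
        morphotype_flag(e, elongation_cut) for e in out["elongation"]
    ]
    if stack is not None and len(out):
        th, tw = stack.tile_shape
        px = stack.scan.pixel_size_um
        n_rows, n_cols = stack.grid_shape
        # halo annuli may straddle tile borders, so evaluate each
        # particle on a mosaic window rather than a single tile
        mosaic = np.full((n_rows * th, n_cols * tw, 3), 255, dtype=np.uint8)
        for tile, (r, c) in zip(stack.tiles, stack.positions):
            mosaic[r * th:(r + 1) * th, c * tw:(c + 1) * tw] = tile
        pad = ring_width_px + 32
        flags = []
        for _, row in out.iterrows():
            r0 = max(int(row["bbox_y0_um"] / px) - pad, 0)
            c0 = max(int(row["bbox_x0_um"] / px) - pad, 0)
            r1 = min(int(np.ceil(row["bbox_y1_um"] / px)) + pad,
                     mosaic.shape[0])
            c1 = min(int(np.ceil(row["bbox_x1_um"] / px)) + pad,
                     mosaic.shape[1])
            window = mosaic[r0:r1, c0:c1]
            flags.append(
                detect_halo(
                    window, row, stack.scan,
                    tile_offset_px=(r0, c0),
                    ring_width_px=ring_width_px, k=halo_k,
                )
            )
        out["has_halo"] = flags
    return out
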