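import numpy as np
import pytest

from particulate import ScanConfig, SceneSpec, render_tiles, sample_truth


@pytest.fixture
def coarse_spec():
    """Small coarse-only scene at the survey noise level (SNR 5)."""

    def make(seed=0, density=5.0, field_mm=2.0, **overrides):
        kwargs = dict(
            field_width_mm=field_mm,
            field_height_mm=field_mm,
            density_per_class={"coarse": density},
            seed=seed,
        )
        kwargs.update(overrides)
        return SceneSpec(**kwargs)

    return make


@pytest.fixture
def quiet_spec(coarse_spec):
    """Noise-free, gradient-free variant for exact-recovery checks."""

    def make(seed=0, **overrides):
        return coarse_spec(seed=seed, noise_sigma=0.0,
                           gradient_amplitude=0.0, halo_fraction=0.0,
                           **overrides)

    return make


@pytest.fixture
def rendered_scene(coarse_spec):
    """(truth, stack) pair for a default noisy coarse scene."""

    def make(seed=0, scan=None, **overrides):
        spec = coarse_spec(seed=seed, **overrides)
        truth = sample_truth(spec)
        stack = render_tiles(
            truth, scan or ScanConfig.low_zoom(),
            metadata=dict(coating="FDTS", holder="H1", lamella="L1"),
        )
        return truth, stack

    return make


def match_to_truth(table, truth, tol_um=5.0):
    """Greedy nearest matching of detections to planted particles."""
    from scipy.spatial import cKDTree

    tx = truth.to_dataframe()
    if len(table) == 0 or len(tx) == 0:
        return np.zeros(len(tx), dtype=bool), np.full(len(tx), -1)
    tree = cKDTree(table[["x_um", "y_um"]].to_numpy())
    d, idx = tree.query(tx[["x_um", "y_um"]].to_numpy())
    matched = d <= tol_um
    return matched, np.where(matched, idx, -1)
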