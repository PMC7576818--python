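"""Detection chain: frame rejection, segmentation, refinement, measurement."""

import numpy as np
import pytest

from particulate import (
    ScanConfig,
    TileStack,
    measure,
    refine_crop,
    reject_frames,
    run_detection,
    sample_truth,
    render_tiles,
    segment_global,
)
from conftest import match_to_truth


def uniform_tile(value=200, shape=(60, 80)):
    return np.full(shape + (3,), value, dtype=np.uint8)


def tile_with_disks(centres, radius=6, value=40, shape=(60, 80), bg=200):
    tile = uniform_tile(bg, shape)
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    for (r, c) in centres:
        inside = (rr - r) ** 2 + (cc - c) ** 2 < radius**2
        tile[inside] = value
    return tile


def make_stack(tiles, scan=None):
    n = len(tiles)
    return TileStack(tiles=tiles, positions=[(0, i) for i in range(n)],
                     scan=scan or ScanConfig(pixel_size_um=1.0,
                                             min_area_um2=20,
                                             max_area_um2=1500))


class TestRejectFrames:
    def test_identical_uniform_tiles_yield_no_rejection(self):
        stack = make_stack([uniform_tile() for _ in range(8)])
        kept, rejected = reject_frames(stack)
        assert rejected == []
        assert len(kept) == 8

    def test_blob_tile_is_the_only_rejection(self):
        tiles = [tile_with_disks([(30, 40)], radius=4) for _ in range(20)]
        blob = uniform_tile()
        blob[10:50, 10:62] = 30  # dark blob over ~30% of the tile
        tiles.append(blob)
        stack = make_stack(tiles)
        means = np.array([t[..., 2].mean() for t in stack.tiles])
        stds = np.array([t[..., 2].std() for t in stack.tiles])
        expect = np.flatnonzero(
            np.abs(means - np.median(means)) > 2 * stds.mean())
        kept, rejected = reject_frames(stack, k=2.0)
        assert rejected == [20]
        assert list(expect) == rejected
        assert len(kept) == 20

    def test_unbounded_tolerance_rejects_nothing(self):
        tiles = [tile_with_disks([(20, 20 + 3 * i)]) for i in range(4)]
        tiles.append(uniform_tile(30))
        _, rejected = reject_frames(make_stack(tiles), k=np.inf)
        assert rejected == []

    def test_empty_stack_is_an_error(self):
        with pytest.raises(Exception):
            reject_frames(TileStack(tiles=[], positions=[]))

    def test_rejection_is_idempotent_after_removal(self):
        tiles = [tile_with_disks([(30, 40)], radius=4) for _ in range(20)]
        blob = uniform_tile()
        blob[:, :] = 60
        tiles.append(blob)
        kept, rejected = reject_frames(make_stack(tiles))
        assert rejected
        kept2, rejected2 = reject_frames(kept)
        assert rejected2 == []
        assert len(kept2) == len(kept)


class TestSegmentGlobal:
    scan = ScanConfig(pixel_size_um=1.0, min_area_um2=20, max_area_um2=1500)

    def test_bright_uniform_tile_gives_empty_mask(self):
        labels = segment_global(uniform_tile(200), self.scan)
        assert labels.max() == 0

    def test_three_disks_give_three_labels(self):
        tile = tile_with_disks([(15, 15), (30, 50), (45, 25)])
        labels = segment_global(tile, self.scan)
        assert labels.max() == 3
        # brute-force: labelled pixels are exactly those below threshold
        assert ((labels > 0) == (tile[..., 2] < 75)).all()

    def test_threshold_boundary_is_strict(self):
        tile = tile_with_disks([(30, 40)], value=75)
        assert segment_global(tile, self.scan).max() == 0
        tile = tile_with_disks([(30, 40)], value=74)
        assert segment_global(tile, self.scan).max() == 1

    def test_small_components_are_discarded(self):
        tile = tile_with_disks([(30, 40)], radius=2)  # ~12 px < 20 um^2
        assert segment_global(tile, self.scan).max() == 0

    def test_non_8bit_input_is_an_error(self):
        with pytest.raises(ValueError):
            segment_global(np.zeros((10, 10, 3), dtype=np.uint16), self.scan)


class TestRefineCrop:
    scan = ScanConfig(pixel_size_um=1.0, min_area_um2=20, max_area_um2=1500)

    def test_uniform_crop_drops_the_candidate(self):
        mask = refine_crop(uniform_tile(), (20, 20, 40, 40), self.scan)
        assert not mask.any()

    def test_disk_refines_to_its_own_pixels(self):
        tile = tile_with_disks([(30, 40)], radius=8)
        disk = tile[..., 2] < 75
        bbox = (22, 32, 39, 49)
        refined = refine_crop(tile, bbox, self.scan)
        # T = 0.6 * crop mean sits between particle (40) and background
        # (200), so the refined mask equals the rendered disk
        assert (refined == disk).all()

    def test_decreasing_alpha_never_grows_the_mask(self):
        tile = tile_with_disks([(30, 40)], radius=8, value=90)
        bbox = (22, 32, 39, 49)
        prev = None
        for alpha in (1.0, 0.8, 0.6, 0.4):
            scan = ScanConfig(pixel_size_um=1.0, min_area_um2=20,
                              max_area_um2=1500, local_alpha=alpha)
            mask = refine_crop(tile, bbox, scan)
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask


class TestMeasure:
    def test_square_has_unit_elongation_and_exact_area(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:15, 8:18] = True
        rec = measure(mask, ScanConfig(pixel_size_um=1.0, min_area_um2=1,
                                       max_area_um2=1500))
        assert rec["area_um2"] == pytest.approx(100.0)
        assert rec["elongation"] == pytest.approx(1.0)
        assert rec["x_um"] == pytest.approx(13.0)
        assert rec["y_um"] == pytest.approx(10.0)

    def test_rectangle_elongation_matches_second_moments(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:20, 5:45] = True  # 40 x 10
        rec = measure(mask, ScanConfig(pixel_size_um=1.0, min_area_um2=1,
                                       max_area_um2=1500))
        assert rec["elongation"] == pytest.approx(4.0, abs=0.05)

    def test_area_scales_with_pixel_size_squared(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:15, 8:18] = True
        scan = ScanConfig(zoom="high", pixel_size_um=0.155,
                          min_area_um2=0.5, max_area_um2=50)
        rec = measure(mask, scan)
        assert rec["area_um2"] == pytest.approx(100 * 0.155**2)

    def test_border_contact_is_flagged(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[0:10, 8:18] = True
        rec = measure(mask, ScanConfig(pixel_size_um=1.0, min_area_um2=1,
                                       max_area_um2=1500))
        assert rec["touches_border"]

    def test_empty_or_multi_component_masks_are_errors(self):
        scan = ScanConfig(pixel_size_um=1.0, min_area_um2=1,
                          max_area_um2=1500)
        with pytest.raises(ValueError):
            measure(np.zeros((10, 10), dtype=bool), scan)
        two = np.zeros((20, 20), dtype=bool)
        two[2:5, 2:5] = True
        two[12:15, 12:15] = True
        with pytest.raises(ValueError):
            measure(two, scan)


class TestRunDetection:
    def test_blank_scene_gives_empty_table(self, quiet_spec):
        spec = quiet_spec(density=0.0)
        stack = render_tiles(sample_truth(spec), ScanConfig.low_zoom())
        table = run_detection(stack)
        assert len(table) == 0

    def test_noise_free_scene_is_recovered_exactly(self, quiet_spec):
        spec = quiet_spec(seed=7, density=8.0)
        truth = sample_truth(spec)
        stack = render_tiles(truth, ScanConfig.low_zoom())
        table = run_detection(stack)
        assert len(table) == len(truth)
        matched, idx = match_to_truth(table, truth)
        assert matched.all()
        df = truth.to_dataframe()
        px_area = 1.55**2
        for i, row in df.iterrows():
            if row.area_um2 / px_area < 25:
                continue
            det = table["area_um2"].iloc[idx[i]]
            assert abs(det - row.area_um2) / row.area_um2 < 0.10

    def test_noisy_scene_recall_with_close_centroids(self, rendered_scene):
        # ~50 planted coarse particles at SNR 5: >= 48 found within 5 um
        truth, stack = rendered_scene(seed=3, density=5.5, field_mm=3.0)
        table = run_detection(stack)
        matched, _ = match_to_truth(table, truth, tol_um=5.0)
        assert len(truth) >= 30
        assert matched.sum() >= len(truth) - 2

    def test_planted_fiber_measures_as_elongated(self, quiet_spec):
        spec = quiet_spec(
            seed=2, density=2.0,
            morphotype_mix={"coarse": {"fiber": 1.0}},
        )
        truth = sample_truth(spec)
        stack = render_tiles(truth, ScanConfig.low_zoom())
        table = run_detection(stack)
        assert len(table) == len(truth) > 0
        assert (table["elongation"] > 5).all()

    def test_output_invariant_to_tile_traversal_order(self, rendered_scene):
        truth, stack = rendered_scene(seed=6)
        table = run_detection(stack)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(stack))
        shuffled = stack.subset(list(order))
        table2 = run_detection(shuffled)
        cols = ["x_um", "y_um", "area_um2", "elongation"]
        assert np.allclose(table[cols].to_numpy(), table2[cols].to_numpy())

    def test_particles_split_across_tiles_are_merged(self):
        # one disk straddling a tile boundary must come back as a single
        # particle with the full area
        scan = ScanConfig(pixel_size_um=1.0, min_area_um2=20,
                          max_area_um2=1500, tile_shape_px=(60, 60))
        mosaic = np.full((60, 120, 3), 200, dtype=np.uint8)
        rr, cc = np.mgrid[:60, :120]
        inside = (rr - 30) ** 2 + (cc - 60) ** 2 < 10**2
        mosaic[inside] = 40
        stack = TileStack(
            tiles=[mosaic[:, :60].copy(), mosaic[:, 60:].copy()],
            positions=[(0, 0), (0, 1)], scan=scan)
        table = run_detection(stack)
        assert len(table) == 1
        assert table["area_um2"].iloc[0] == pytest.approx(int(inside.sum()),
                                                          rel=0.02)
        assert table["x_um"].iloc[0] == pytest.approx(60.0, abs=1.0)
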