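"""Contamination statistics: densities, CSFs, t-tests, coverage, SCP."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from particulate import (
    SizeLaw,
    cleanliness_class,
    compare_coatings,
    cumulative_size_function,
    density,
    extrapolate_coverage,
    histogram_mode,
    summary_grid,
    t_test_unpaired,
)


def table_from_positions(xs, ys):
    return pd.DataFrame({"x_um": xs, "y_um": ys})


class TestDensity:
    def test_count_over_area(self):
        xs = np.linspace(0, 1000, 400)
        d, _ = density(table_from_positions(xs, xs), 244.0)
        assert d == pytest.approx(400 / 244.0)

    def test_empty_table_is_zero(self):
        d, sd = density(table_from_positions([], []), 244.0)
        assert d == 0.0 and sd == 0.0

    def test_dispersion_from_tile_partition(self):
        rng = np.random.default_rng(3)
        xs = rng.uniform(0, 2000, 200)
        ys = rng.uniform(0, 2000, 200)
        tiles = [(i * 500.0, j * 500.0, (i + 1) * 500.0, (j + 1) * 500.0)
                 for i in range(4) for j in range(4)]
        d, sd = density(table_from_positions(xs, ys), 4.0, tiles)
        per_tile = []
        for x0, y0, x1, y1 in tiles:
            n = ((xs >= x0) & (xs < x1) & (ys >= y0) & (ys < y1)).sum()
            per_tile.append(n / 0.25)
        assert d == pytest.approx(50.0)
        assert sd == pytest.approx(np.std(per_tile, ddof=1) / 4.0)

    def test_zero_area_is_an_error(self):
        with pytest.raises(ValueError):
            density(table_from_positions([1.0], [1.0]), 0.0)


class TestSummaryGrid:
    def test_identical_cells_have_zero_spread(self):
        cells = {(c, h): 2.0 for c in "ABC" for h in "XYZ"}
        grid = summary_grid(cells)
        for mean, sd in grid.row_means.values():
            assert mean == 2.0 and sd == 0.0
        for mean, sd in grid.col_means.values():
            assert mean == 2.0 and sd == 0.0

    def test_marginals_are_arithmetic_means(self):
        cells = {("A", "X"): 1.0, ("A", "Y"): 2.0,
                 ("B", "X"): 3.0, ("B", "Y"): 5.0}
        grid = summary_grid(cells)
        assert grid.row_means["A"][0] == pytest.approx(1.5)
        assert grid.col_means["Y"][0] == pytest.approx(3.5)
        frame = grid.to_frame()
        assert frame.loc["A", "<d>"] == pytest.approx(1.5)

    def test_missing_cell_is_an_error(self):
        cells = {("A", "X"): 1.0, ("A", "Y"): 2.0, ("B", "X"): 3.0}
        with pytest.raises(ValueError):
            summary_grid(cells)


class TestCumulativeSizeFunction:
    def test_all_equal_areas_step_at_that_area(self):
        csf = cumulative_size_function([100.0] * 20, (50.0, 1500.0))
        below = csf.bin_edges < 100.0
        assert (csf.cum_fraction[below] == 0).all()
        assert (csf.cum_fraction[~below] == 100.0).all()

    def test_final_value_is_total_percentage(self):
        rng = np.random.default_rng(1)
        areas = rng.uniform(50, 1500, 333)
        csf = cumulative_size_function(areas, (50.0, 1500.0))
        assert csf.cum_fraction[-1] == 100.0

    def test_matches_empirical_cdf_at_midpoint(self):
        rng = np.random.default_rng(5)
        areas = rng.uniform(50, 1500, 1000)
        csf = cumulative_size_function(areas, (50.0, 1500.0), n_bins=50)
        mid = np.sqrt(50.0 * 1500.0)
        i = np.argmin(np.abs(csf.bin_edges - mid))
        expect = 100.0 * (areas <= csf.bin_edges[i]).mean()
        assert csf.cum_fraction[i] == pytest.approx(expect)

    def test_empty_area_list_is_an_error(self):
        with pytest.raises(ValueError):
            cumulative_size_function([], (50.0, 1500.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=50.0, max_value=1500.0),
                    min_size=1, max_size=60),
           st.integers(min_value=2, max_value=40))
    def test_monotone_and_bounded(self, areas, n_bins):
        csf = cumulative_size_function(areas, (50.0, 1500.0), n_bins=n_bins)
        assert (np.diff(csf.cum_fraction) >= 0).all()
        assert csf.cum_fraction[0] >= 0
        assert csf.cum_fraction[-1] == 100.0


class TestHistogramMode:
    def test_peak_bin_centre(self):
        areas = [60.0] * 3 + [120.0] * 10 + [400.0] * 2
        assert histogram_mode(areas) == 125.0


class TestTTest:
    def test_identical_samples(self):
        t, df, p = t_test_unpaired([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0 and p == 1.0 and df == 6

    def test_separated_samples(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1e-3, 4)
        b = 1 + rng.normal(0, 1e-3, 4)
        _, _, p = t_test_unpaired(a, b)
        assert p < 0.001

    def test_zero_variance_cases(self):
        t, df, p = t_test_unpaired([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        with pytest.warns(RuntimeWarning):
            t, df, p = t_test_unpaired([0.0, 0.0], [1.0, 1.0])
        assert p == 0.0

    def test_matches_reference_implementation(self):
        from scipy import stats as sps

        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 10), rng.normal(0.4, 1.3, 14)
        t, df, p = t_test_unpaired(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        assert df == 22

    def test_too_small_samples_raise(self):
        with pytest.raises(ValueError):
            t_test_unpaired([1.0], [1.0, 2.0])


def _csf_set(rng, mode, n_holders=3, n=300):
    law = SizeLaw(mode, 0.4, 50.0, 1500.0)
    return {
        f"H{i}": cumulative_size_function(law.sample(n, rng), (50.0, 1500.0))
        for i in range(n_holders)
    }


class TestCompareCoatings:
    def test_identical_functions_give_p_one(self):
        csf = cumulative_size_function([100.0, 200.0, 400.0] * 10,
                                       (50.0, 1500.0))
        csfs = {"A": {"H1": csf, "H2": csf}, "B": {"H1": csf, "H2": csf}}
        res = compare_coatings(csfs, (50.0, 1500.0))
        assert res[("A", "B")]["p"] == 1.0

    def test_planted_disjoint_modes_are_significant(self):
        rng = np.random.default_rng(21)
        csfs = {"A": _csf_set(rng, 120.0), "B": _csf_set(rng, 600.0)}
        res = compare_coatings(csfs, (50.0, 1500.0))
        assert res[("A", "B")]["p"] < 0.01

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(2)
        set_a, set_b = _csf_set(rng, 150.0), _csf_set(rng, 200.0)
        res1 = compare_coatings({"A": set_a, "B": set_b}, (50.0, 1500.0))
        res2 = compare_coatings({"B": set_a, "A": set_b}, (50.0, 1500.0))
        assert res1[("A", "B")]["p"] == pytest.approx(res2[("A", "B")]["p"])
        assert res1[("A", "B")]["t"] == pytest.approx(-res2[("A", "B")]["t"])

    def test_single_holder_coating_is_an_error(self):
        rng = np.random.default_rng(3)
        csfs = {"A": _csf_set(rng, 150.0, n_holders=1),
                "B": _csf_set(rng, 150.0)}
        with pytest.raises(ValueError):
            compare_coatings(csfs, (50.0, 1500.0))

    def test_empty_range_is_an_error(self):
        rng = np.random.default_rng(4)
        csfs = {"A": _csf_set(rng, 150.0), "B": _csf_set(rng, 150.0)}
        with pytest.raises(ValueError):
            compare_coatings(csfs, (900.0, 200.0))


class TestExtrapolateCoverage:
    params = {
        "coarse": (1.6, SizeLaw(155.0, 0.7, 50.0, 1500.0)),
        "fine": (3.3, SizeLaw(2.0, 1.0, 0.5, 50.0)),
    }

    def test_zero_horizon_gives_zero_coverage(self):
        assert extrapolate_coverage(self.params, 0).coverage_percent == 0.0

    def test_linear_in_horizon(self):
        c20 = extrapolate_coverage(self.params, 20).coverage_percent
        c40 = extrapolate_coverage(self.params, 40).coverage_percent
        assert c40 == pytest.approx(2 * c20)

    def test_matches_monte_carlo_planted_coverage(self):
        # forecast vs sum of planted areas / field area, 10 seeds
        from particulate import SceneSpec, sample_truth

        horizon = 40
        forecast = extrapolate_coverage(self.params, horizon)
        covs = []
        for seed in range(10):
            spec = SceneSpec(
                field_width_mm=10.0, field_height_mm=10.0,
                density_per_class={"coarse": 1.6, "fine": 3.3},
                seed=seed)
            truth = sample_truth(spec)
            planted = truth.areas().sum()  # um^2 over 100 mm^2
            covs.append(100.0 * horizon * planted / (100.0 * 1e6))
        assert np.mean(covs) == pytest.approx(forecast.coverage_percent,
                                              rel=0.05)

    def test_negative_horizon_is_an_error(self):
        with pytest.raises(ValueError):
            extrapolate_coverage(self.params, -1)


class TestCleanlinessClass:
    @pytest.mark.parametrize("dens,cls", [
        (1e6, 6),
        (9.9e5, 6),
        (1.01e6, 7),
        (5e3, 4),
        (0.0, 0),
        (0.5, 0),
    ])
    def test_log_decade_rule(self, dens, cls):
        assert cleanliness_class(dens) == cls

    def test_negative_density_is_an_error(self):
        with pytest.raises(ValueError):
            cleanliness_class(-1.0)
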