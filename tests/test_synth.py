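"""Synthetic generators: determinism, stated ranges, and known-truth rules."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.special import expit

import hiersdm as h
from hiersdm import synth
from hiersdm.synth import (GRASSLAND, IMPERVIOUS, UrbanGrowthRule,
                           bio9_gradient, make_lulc_series,
                           make_national_environment, make_protected_areas,
                           make_provincial_environment, national_truth,
                           sample_occurrences, true_suitability)


@pytest.fixture(scope="module")
def nat_grid():
    return h.GridSpec(40, 50, 100.0, 40.0, 0.25, crs_tag="lonlat")


@pytest.fixture(scope="module")
def prov_grid():
    return h.GridSpec(60, 60, 0.0, 18000.0, 300.0)


class TestNationalEnvironment:
    def test_deterministic_per_seed(self, nat_grid):
        a = make_national_environment(nat_grid, 42)
        b = make_national_environment(nat_grid, 42)
        for name in a:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_different_seeds_differ(self, nat_grid):
        a = make_national_environment(nat_grid, 1)
        b = make_national_environment(nat_grid, 2)
        assert not np.array_equal(a["bio9"].values, b["bio9"].values)

    def test_gradient_component_monotone_north_to_south(self, nat_grid):
        grad = bio9_gradient(nat_grid)
        row_means = grad.mean(axis=1)
        assert (np.diff(row_means) > 0).all()  # row 0 = north = coldest
        assert row_means[0] == pytest.approx(-15.0)
        assert row_means[-1] == pytest.approx(20.0)

    def test_value_ranges(self, nat_grid):
        s = make_national_environment(nat_grid, 3)
        assert s["bio9"].values.min() >= -15 - 5
        assert s["bio9"].values.max() <= 20 + 5
        assert s["bio14"].values.min() >= 0.0
        assert s["bio14"].values.max() <= 100.0
        assert set(np.unique(s["lulc"].values)) <= set(synth.LULC_CLASSES)

    def test_small_grid_rejected(self):
        tiny = h.GridSpec(10, 10, 0.0, 1000.0, 100.0)
        with pytest.raises(ValueError, match="too small"):
            make_national_environment(tiny, 0)


class TestTruthModel:
    def test_all_zero_coefficients_give_half(self, nat_grid):
        stack = make_national_environment(nat_grid, 1)
        flat = synth.TruthModel()  # eta = 0 everywhere
        suit = true_suitability(stack, flat)
        np.testing.assert_allclose(suit.values, 0.5)

    def test_bio9_at_optimum_maximises_its_term(self, nat_grid):
        truth = national_truth()
        stack = make_national_environment(nat_grid, 1)
        stack["bio9"] = stack["bio9"].with_values(
            np.full(nat_grid.shape, truth.optimum_bio9))
        at_opt = true_suitability(stack, truth)
        stack["bio9"] = stack["bio9"].with_values(
            np.full(nat_grid.shape, truth.optimum_bio9 + 3.0))
        off_opt = true_suitability(stack, truth)
        assert (at_opt.values >= off_opt.values).all()

    def test_marginal_argmax_matches_optimum_by_scan(self, nat_grid):
        # brute-force scan of the bio9 marginal on a fine grid of values
        truth = national_truth()
        grid_vals = np.linspace(-15, 20, 701)
        eta = truth.intercept + truth.quadratic["bio9"] * (
            grid_vals - truth.optimum["bio9"]) ** 2
        marginal = expit(eta)
        argmax = grid_vals[int(np.argmax(marginal))]
        assert abs(argmax - truth.optimum_bio9) <= (35 / 700) + 1e-12

    def test_bio14_marginal_flat_below_threshold(self):
        truth = national_truth()
        thr = truth.ramp_threshold["bio14"]
        below = truth.ramp_slope["bio14"] * np.clip(
            np.array([0.0, thr / 2, thr]) - thr, 0, None)
        assert (below == 0).all()

    def test_missing_predictor_raises(self, nat_grid):
        stack = make_national_environment(nat_grid, 1)
        del stack["bio9"]
        with pytest.raises(KeyError, match="bio9"):
            true_suitability(stack, national_truth())


class TestSampleOccurrences:
    def test_single_positive_cell(self, prov_grid):
        v = np.zeros(prov_grid.shape)
        v[7, 9] = 1.0
        suit = h.Raster(prov_grid, v)
        occ = sample_occurrences(suit, 1, 0)
        x, y = prov_grid.cell_center(7, 9)
        assert occ.points == [(float(x), float(y))]

    def test_deterministic(self, prov_grid):
        suit = h.Raster(prov_grid, np.full(prov_grid.shape, 0.5))
        a = sample_occurrences(suit, 50, 11)
        b = sample_occurrences(suit, 50, 11)
        assert a.points == b.points

    def test_uniform_suitability_yields_uniform_cells(self):
        # chi-square goodness of fit over a coarse partition of the grid
        g = h.GridSpec(20, 20, 0.0, 2000.0, 100.0)
        suit = h.Raster(g, np.ones(g.shape))
        occ = sample_occurrences(suit, 300, 7)
        x, y = occ.as_arrays()
        rows, cols = g.cell_index(x, y)
        quadrant = (rows >= 10).astype(int) * 2 + (cols >= 10).astype(int)
        counts = np.bincount(quadrant, minlength=4)
        from scipy.stats import chisquare
        assert chisquare(counts).pvalue > 0.001

    def test_n_exceeding_positive_cells_raises(self, prov_grid):
        v = np.zeros(prov_grid.shape)
        v[0, :3] = 1.0
        with pytest.raises(ValueError, match="exceeds"):
            sample_occurrences(h.Raster(prov_grid, v), 4, 0)


class TestProvincialEnvironment:
    def test_deterministic(self, prov_grid):
        a = make_provincial_environment(prov_grid, 5)
        b = make_provincial_environment(prov_grid, 5)
        for name in a:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_dist_water_zero_on_river_and_cell_size_adjacent(self, prov_grid):
        s = make_provincial_environment(prov_grid, 5)
        d = s["dist_water"].values
        assert d.min() == 0.0
        # some cell directly north/south of a river cell sits one cell away
        assert (d == prov_grid.cell_size).any()

    def test_slope_zero_for_constant_elevation(self, prov_grid):
        # recompute the slope rule on a constant field: finite differences
        # of a constant are zero, so slope must be identically zero
        z = np.full(prov_grid.shape, 800.0)
        dzdy, dzdx = np.gradient(z, prov_grid.cell_size, prov_grid.cell_size)
        slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
        assert (slope == 0).all()

    def test_slope_matches_finite_difference_oracle(self, prov_grid):
        s = make_provincial_environment(prov_grid, 5)
        z = s["elevation"].values
        dzdy, dzdx = np.gradient(z, prov_grid.cell_size, prov_grid.cell_size)
        expected = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
        np.testing.assert_allclose(s["slope"].values, expected)

    def test_aspect_range(self, prov_grid):
        s = make_provincial_environment(prov_grid, 5)
        assert s["aspect"].values.min() >= 0.0
        assert s["aspect"].values.max() < 360.0


class TestLulcSeries:
    def test_zero_growth_is_static(self, prov_grid):
        rule = UrbanGrowthRule(base_distance=0.0, growth_per_step=0.0)
        series = make_lulc_series(prov_grid, 3, rule=rule)
        np.testing.assert_array_equal(series.maps["t0"].values,
                                      series.maps["t1"].values)
        np.testing.assert_array_equal(series.maps["t1"].values,
                                      series.maps["t2"].values)

    def test_impervious_count_non_decreasing(self, prov_grid):
        series = make_lulc_series(prov_grid, 3)
        counts = [(series.maps[t].values == IMPERVIOUS).sum()
                  for t in ("t0", "t1", "t2")]
        assert counts[0] <= counts[1] <= counts[2]

    def test_converted_cells_exactly_satisfy_distance_rule(self, prov_grid):
        series = make_lulc_series(prov_grid, 3)
        t0, t1 = series.maps["t0"].values, series.maps["t1"].values
        # independent recomputation: distance to the t0 urban core
        core = np.zeros(prov_grid.shape, dtype=bool)
        r0, c0 = prov_grid.n_rows // 2, prov_grid.n_cols // 2
        core[r0 - 3:r0 + 3, c0 - 3:c0 + 3] = True
        dist = ndimage.distance_transform_edt(~core) * prov_grid.cell_size
        radius = series.rule.base_distance + series.rule.growth_per_step
        expected_converted = (t0 == GRASSLAND) & (dist <= radius)
        actually_converted = (t0 != t1)
        np.testing.assert_array_equal(actually_converted, expected_converted)


class TestFutureClimate:
    def test_identity_scenario(self, nat_grid):
        stack = make_national_environment(nat_grid, 1)
        sc = synth.ScenarioSpec("SSP126", "2030s", 0.0, 1.0)
        out = synth.make_future_climate(stack, sc)
        for name in stack:
            np.testing.assert_array_equal(out[name].values, stack[name].values)

    def test_delta_shifts_bio9_mean_exactly(self, nat_grid):
        stack = make_national_environment(nat_grid, 1)
        sc = synth.ScenarioSpec("SSP585", "2030s", 1.5, 1.0)
        out = synth.make_future_climate(stack, sc)
        assert out["bio9"].values.mean() - stack["bio9"].values.mean() == \
            pytest.approx(1.5)
        np.testing.assert_array_equal(out["lulc"].values, stack["lulc"].values)

    def test_warming_moves_truth_suitability_north(self, nat_grid):
        stack = make_national_environment(nat_grid, 1)
        truth = national_truth()
        sc = synth.ScenarioSpec("SSP585", "2050s", 2.5, 1.0)
        warmed = synth.make_future_climate(stack, sc)
        cur = true_suitability(stack, truth)
        fut = true_suitability(warmed, truth)
        lat = nat_grid.row_center_latitudes()
        cur_center = (cur.values.sum(axis=1) * lat).sum() / cur.values.sum()
        fut_center = (fut.values.sum(axis=1) * lat).sum() / fut.values.sum()
        assert fut_center > cur_center

    def test_scenario_deltas_ordered_within_period(self):
        for period in ("2030s", "2050s"):
            deltas = [s.temperature_delta for s in synth.DEFAULT_SCENARIOS
                      if s.period == period]
            assert deltas == sorted(deltas)


class TestProtectedAreas:
    def test_fraction_zero_empty(self, prov_grid):
        assert make_protected_areas(prov_grid, 0.0, 0).values.sum() == 0

    def test_fraction_one_full(self, prov_grid):
        r = make_protected_areas(prov_grid, 1.0, 0)
        assert r.values.sum() == prov_grid.n_rows * prov_grid.n_cols

    def test_fraction_point_one_within_tolerance(self):
        g = h.GridSpec(100, 100, 0.0, 10000.0, 100.0)
        r = make_protected_areas(g, 0.1, 9)
        share = r.values.sum() / 1e4
        assert 0.09 <= share <= 0.11

    def test_deterministic(self, prov_grid):
        a = make_protected_areas(prov_grid, 0.05, 4)
        b = make_protected_areas(prov_grid, 0.05, 4)
        np.testing.assert_array_equal(a.values, b.values)
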