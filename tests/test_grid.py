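"""Raster model: I/O round trips, resampling, areas, overlays, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hiersdm as h
from hiersdm.grid import EARTH_RADIUS_KM


class TestIO:
    def test_round_trip_zeros(self, small_grid, tmp_path):
        r = h.Raster(small_grid, np.zeros((5, 5)))
        back = h.read_raster(h.write_raster(r, tmp_path / "z.grd"))
        assert back.grid == r.grid
        assert back.kind == "continuous"
        np.testing.assert_array_equal(back.values, r.values)

    def test_round_trip_is_bit_exact_for_floats(self, small_grid, tmp_path):
        rng = np.random.default_rng(0)
        r = h.Raster(small_grid, rng.standard_normal((5, 5)) * 1e6)
        back = h.read_raster(h.write_raster(r, tmp_path / "f.grd"))
        assert (back.values == r.values).all()  # bit-exact, not approx

    def test_nodata_mask_preserved(self, small_grid, tmp_path):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = True
        r = h.Raster(small_grid, np.ones((5, 5)), mask)
        back = h.read_raster(h.write_raster(r, tmp_path / "m.grd"))
        np.testing.assert_array_equal(back.nodata_mask, mask)

    def test_categorical_codes_round_trip_as_integers(self, small_grid, tmp_path):
        codes = np.arange(25).reshape(5, 5) % 6 + 1
        r = h.Raster(small_grid, codes, kind="categorical")
        back = h.read_raster(h.write_raster(r, tmp_path / "c.grd"))
        assert back.values.dtype == np.int64
        np.testing.assert_array_equal(back.values, codes)

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.grd"
        bad.write_text("not a grid\n")
        with pytest.raises(ValueError, match="magic"):
            h.read_raster(bad)

    def test_multi_band_header_rejected(self, small_grid, tmp_path):
        p = h.write_raster(h.Raster(small_grid, np.zeros((5, 5))),
                           tmp_path / "b.grd")
        text = p.read_text().replace('"n_bands": 1', '"n_bands": 3')
        p.write_text(text)
        with pytest.raises(ValueError, match="3 bands"):
            h.read_raster(p)


class TestRasterInvariants:
    def test_binary_values_restricted(self, small_grid):
        with pytest.raises(ValueError, match="outside"):
            h.Raster(small_grid, np.full((5, 5), 2), kind="binary")

    def test_shape_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError, match="shape"):
            h.Raster(small_grid, np.zeros((4, 5)))


class TestResample:
    def test_identity_on_own_grid(self, small_grid):
        r = h.Raster(small_grid, np.arange(25.0).reshape(5, 5))
        out = h.resample_nearest(r, small_grid)
        np.testing.assert_array_equal(out.values, r.values)

    def test_coarse_to_fine_block_refinement(self):
        coarse = h.GridSpec(2, 2, 0.0, 2000.0, 1000.0)
        fine = h.GridSpec(4, 4, 0.0, 2000.0, 500.0)
        r = h.Raster(coarse, np.array([[1, 0], [0, 1]]), kind="binary")
        out = h.resample_nearest(r, fine)
        expected = np.array([
            [1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1],
        ])
        np.testing.assert_array_equal(out.values, expected)
        assert out.kind == "binary"

    def test_boundary_center_uses_half_open_convention(self):
        # fine cells of size 500 shifted so one center lands exactly on the
        # coarse cell boundary x=1000: the cell owning its left edge wins
        coarse = h.GridSpec(1, 2, 0.0, 500.0, 1000.0)
        r = h.Raster(coarse, np.array([[3.0, 7.0]]))
        fine = h.GridSpec(1, 1, 750.0, 500.0, 500.0)  # center x=1000
        out = h.resample_nearest(r, fine)
        assert out.values[0, 0] == 7.0

    def test_no_new_values_invented(self, small_grid):
        rng = np.random.default_rng(3)
        r = h.Raster(small_grid, (rng.random((5, 5)) * 6).astype(int) + 1,
                     kind="categorical")
        fine = h.GridSpec(10, 10, 0.0, 5000.0, 500.0)
        out = h.resample_nearest(r, fine)
        assert set(np.unique(out.values)) <= set(np.unique(r.values))

    def test_disjoint_extents_raise(self, small_grid):
        r = h.Raster(small_grid, np.zeros((5, 5)))
        far = h.GridSpec(5, 5, 1e7, 1e7, 1000.0)
        with pytest.raises(ValueError, match="disjoint"):
            h.resample_nearest(r, far)


class TestArea:
    def test_all_zero_is_zero(self, small_grid, make_binary):
        assert h.area_km2(make_binary(small_grid, np.zeros((5, 5)))) == 0.0

    def test_ten_cells_at_300m(self, make_binary):
        g = h.GridSpec(5, 5, 0.0, 1500.0, 300.0)
        v = np.zeros((5, 5))
        v.ravel()[:10] = 1
        assert h.area_km2(make_binary(g, v)) == pytest.approx(10 * 0.09)

    def test_full_grid_of_10km_cells(self, make_binary):
        g = h.GridSpec(2, 2, 0.0, 20000.0, 10000.0)
        assert h.area_km2(make_binary(g, np.ones((2, 2)))) == pytest.approx(400.0)

    def test_lonlat_uses_cos_weighting(self, make_binary):
        g = h.GridSpec(1, 1, 100.0, 40.0, 1.0, crs_tag="lonlat")
        a = h.area_km2(make_binary(g, np.ones((1, 1))))
        deg_km = np.deg2rad(1.0) * EARTH_RADIUS_KM
        assert a == pytest.approx(deg_km**2 * np.cos(np.deg2rad(39.5)))

    def test_non_binary_rejected(self, small_grid):
        with pytest.raises(ValueError, match="binary"):
            h.area_km2(h.Raster(small_grid, np.zeros((5, 5))))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**25 - 1))
    def test_additive_over_disjoint_masks(self, bits):
        g = h.GridSpec(5, 5, 104.0, 39.0, 0.1, crs_tag="lonlat")
        sel = np.array([(bits >> k) & 1 for k in range(25)]).reshape(5, 5)
        a = h.Raster(g, sel, kind="binary")
        b = h.Raster(g, 1 - sel, kind="binary")
        both = h.Raster(g, np.ones((5, 5), dtype=int), kind="binary")
        assert h.area_km2(a) + h.area_km2(b) == pytest.approx(h.area_km2(both))


class TestOverlay:
    def test_idempotent_identity_absorbing(self, small_grid, make_binary):
        rng = np.random.default_rng(1)
        a = make_binary(small_grid, rng.integers(0, 2, (5, 5)))
        ones = make_binary(small_grid, np.ones((5, 5)))
        zeros = make_binary(small_grid, np.zeros((5, 5)))
        np.testing.assert_array_equal(h.overlay_and(a, a).values, a.values)
        np.testing.assert_array_equal(h.overlay_and(a, ones).values, a.values)
        np.testing.assert_array_equal(h.overlay_and(a, zeros).values, 0)

    def test_nodata_propagates(self, small_grid, make_binary):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        a = make_binary(small_grid, np.ones((5, 5)), mask)
        b = make_binary(small_grid, np.ones((5, 5)))
        out = h.overlay_and(a, b)
        assert out.nodata_mask[2, 2]
        assert out.values[2, 2] == 0  # nodata never counts as suitable

    def test_grid_mismatch_raises(self, small_grid, make_binary):
        other = h.GridSpec(5, 5, 0.0, 5000.0, 500.0)
        a = make_binary(small_grid, np.ones((5, 5)))
        b = make_binary(other, np.ones((5, 5)))
        with pytest.raises(ValueError, match="identical GridSpec"):
            h.overlay_and(a, b)


class TestLatitudinalProfile:
    def test_single_cell_lands_in_its_band(self, make_binary):
        g = h.GridSpec(1, 1, 105.0, 34.2, 0.1, crs_tag="lonlat")  # center 34.15
        prof = h.latitudinal_profile(make_binary(g, np.ones((1, 1))), 0.1)
        peak = prof.peak_band
        assert peak == pytest.approx(34.1)
        assert prof.total_area > 0

    def test_uniform_grid_band_areas_follow_cos_weighting(self, lonlat_grid,
                                                          make_binary):
        prof = h.latitudinal_profile(
            make_binary(lonlat_grid, np.ones((40, 40))), 0.1)
        # cells are 0.1 degrees, so one row per band; areas decrease northward
        nonzero = prof.band_area[prof.band_area > 0]
        assert (np.diff(nonzero) < 0).all()  # sorted south -> north by edges

    def test_band_areas_sum_to_total(self, lonlat_grid, make_binary):
        rng = np.random.default_rng(5)
        r = make_binary(lonlat_grid, rng.integers(0, 2, (40, 40)))
        prof = h.latitudinal_profile(r, 0.1)
        cell_area = r.grid.cell_area_km2().max()
        assert abs(prof.total_area - h.area_km2(r)) <= cell_area

    def test_equal_peaks_tie_reports_southernmost(self):
        prof = h.LatBandProfile(
            band_lower_edges=np.array([31.0, 35.0, 39.0]),
            band_area=np.array([50.0, 10.0, 50.0]),
            bandwidth=0.1,
        )
        assert prof.peak_band == 31.0

    def test_two_cluster_profile_separates_bands(self, make_binary):
        g = h.GridSpec(20, 10, 104.0, 39.0, 0.1, crs_tag="lonlat")
        v = np.zeros((20, 10))
        v[1, :3] = 1    # cluster near 38.85
        v[18, :3] = 1   # cluster near 37.15
        prof = h.latitudinal_profile(make_binary(g, v), 0.1)
        assert (prof.band_area > 0).sum() == 2

    def test_requires_lonlat(self, small_grid, make_binary):
        with pytest.raises(ValueError, match="lonlat"):
            h.latitudinal_profile(make_binary(small_grid, np.ones((5, 5))), 0.1)
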