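import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hippogradients.connectivity import (
    TimeSeries,
    connectivity_matrix,
    fisher_z,
    group_average,
    max_connectivity_map,
    parcellate_timeseries,
    regress_global_mean,
    sector_connectivity,
    smooth_flatmap_timeseries,
    tsnr_map,
)
from hippogradients.grids import make_flatmap_grid


def ts(values, kind="cortical-parcel"):
    return TimeSeries(np.asarray(values, dtype=float), kind)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_unit_correlation_is_clipped_finite(self):
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))
        assert np.isfinite(fisher_z(-1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    @given(st.floats(-1.0, 1.0))
    @settings(derandomize=True, max_examples=50)
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)


class TestRegressGlobalMean:
    def test_identical_rows_become_zero(self):
        x = ts(np.tile([1.0, 2.0, 3.0, 1.0], (4, 1)))
        out = regress_global_mean(x)
        assert np.abs(out.values).max() < 1e-12

    def test_orthogonal_zero_mean_row_unchanged(self):
        m = np.array([1.0, -1.0, 1.0, -1.0])
        row = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to m, zero-mean
        x = ts(np.vstack([row, 2 * m - row]))  # spatial mean series = m
        out = regress_global_mean(x)
        assert np.allclose(out.values[0], row, atol=1e-12)

    def test_residuals_uncorrelated_with_mean(self, rng):
        x = ts(rng.standard_normal((5, 20)))
        out = regress_global_mean(x)
        m = x.values.mean(axis=0)
        for row in out.values:
            r = np.corrcoef(row, m)[0, 1]
            assert abs(r) < 1e-10

    def test_idempotent(self, rng):
        x = ts(rng.standard_normal((6, 30)))
        once = regress_global_mean(x)
        twice = regress_global_mean(once)
        assert np.abs(once.values - twice.values).max() < 1e-10

    def test_constant_mean_falls_back_to_intercept(self):
        x = ts(np.vstack([[1.0, 1, 1, 1], [-1.0, -1, -1, -1], [0.5, 0.5, 0.5, 0.5]]))
        with pytest.warns(RuntimeWarning):
            out = regress_global_mean(x)
        assert np.abs(out.values).max() < 1e-12


class TestParcellate:
    def test_singleton_parcels_identity_up_to_order(self, rng):
        x = ts(rng.standard_normal((4, 10)), "cortical-vertex")
        out = parcellate_timeseries(x, [3, 1, 0, 2])
        assert np.allclose(out.values, x.values[[2, 1, 3, 0]])

    def test_mean_of_members(self):
        x = ts([[1.0, 2.0], [3.0, 4.0]], "cortical-vertex")
        out = parcellate_timeseries(x, [0, 0])
        assert np.allclose(out.values, [[2.0, 3.0]])

    def test_identical_members_equal_member(self):
        x = ts([[1.0, 5.0, 2.0], [1.0, 5.0, 2.0]], "cortical-vertex")
        out = parcellate_timeseries(x, [0, 0])
        assert np.allclose(out.values[0], x.values[0])

    def test_empty_expected_parcel_named(self):
        x = ts([[1.0, 2.0], [3.0, 4.0]], "cortical-vertex")
        with pytest.raises(ValueError, match="parcel 2"):
            parcellate_timeseries(x, [0, 1], expected_labels=[0, 1, 2])


class TestConnectivityMatrix:
    def test_self_connectivity_symmetric(self, rng):
        x = ts(rng.standard_normal((3, 25)))
        C = connectivity_matrix(x, x)
        assert np.abs(C.values - C.values.T).max() < 1e-10

    def test_perfect_and_anti_correlation_clipped(self):
        a = ts([[1.0, 2.0, 3.0]])
        b = ts([[2.0, 4.0, 6.0]])
        c = ts([[3.0, 2.0, 1.0]])
        assert connectivity_matrix(a, b).values[0, 0] == pytest.approx(np.arctanh(1 - 1e-7))
        assert connectivity_matrix(a, c).values[0, 0] == pytest.approx(np.arctanh(-1 + 1e-7))

    def test_permutation_equivariance(self, rng):
        x = ts(rng.standard_normal((5, 30)))
        perm = [4, 2, 0, 1, 3]
        xp = ts(x.values[perm])
        C = connectivity_matrix(x, x).values
        Cp = connectivity_matrix(xp, xp).values
        assert np.allclose(Cp, C[np.ix_(perm, perm)])

    def test_zero_variance_row_warns_and_zeroes(self, rng):
        vals = rng.standard_normal((3, 10))
        vals[1] = 2.0
        x = ts(vals)
        y = ts(rng.standard_normal((2, 10)))
        with pytest.warns(RuntimeWarning):
            C = connectivity_matrix(x, y)
        assert np.allclose(C.values[1], 0.0)


class TestGroupAverage:
    def test_single_matrix_is_itself(self, rng):
        x = ts(rng.standard_normal((3, 20)))
        C = connectivity_matrix(x, x)
        avg = group_average([C])
        assert np.array_equal(avg.values, C.values)
        assert avg.averaged_over == 1

    def test_matches_brute_force_loop(self, rng):
        mats = [connectivity_matrix(ts(rng.standard_normal((4, 15))),
                                    ts(rng.standard_normal((3, 15))))
                for _ in range(3)]
        avg = group_average(mats)
        expect = np.zeros_like(avg.values)
        for m in mats:
            expect += m.values
        expect /= 3
        assert np.allclose(avg.values, expect)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            group_average([])


class TestMaps:
    def test_max_map_equals_brute_force(self, rng):
        from hippogradients.connectivity import ConnectivityMatrix

        vals = rng.standard_normal((20, 50))
        C = ConnectivityMatrix(vals, "hippocampal-vertex", "cortical-vertex")
        m = max_connectivity_map(C)
        assert np.array_equal(m, np.array([vals[:, j].max() for j in range(50)]))

    def test_max_map_single_row(self):
        from hippogradients.connectivity import ConnectivityMatrix

        C = ConnectivityMatrix(np.array([[0.1, -0.5, 0.3]]),
                               "hippocampal-vertex", "cortical-vertex")
        assert np.array_equal(max_connectivity_map(C), [0.1, -0.5, 0.3])

    def test_sector_maps_on_2x2_grid_are_vertex_rows(self, rng):
        grid = make_flatmap_grid(2, 2)
        hip = ts(rng.standard_normal((4, 40)), "hippocampal-vertex")
        ctx = ts(rng.standard_normal((6, 40)), "cortical-parcel")
        maps = sector_connectivity(hip, ctx, grid)
        dense = connectivity_matrix(hip, ctx).values
        # vertex order row-major: (0,0)=post-med, (0,1)=post-lat, (1,0)=ant-med, (1,1)=ant-lat
        assert np.allclose(maps["posterior-medial"], dense[0])
        assert np.allclose(maps["posterior-lateral"], dense[1])
        assert np.allclose(maps["anterior-medial"], dense[2])
        assert np.allclose(maps["anterior-lateral"], dense[3])

    def test_identical_hippocampal_series_give_identical_sector_maps(self, rng):
        grid = make_flatmap_grid(2, 2)
        row = rng.standard_normal(30)
        hip = ts(np.tile(row, (4, 1)), "hippocampal-vertex")
        ctx = ts(rng.standard_normal((5, 30)), "cortical-parcel")
        maps = sector_connectivity(hip, ctx, grid)
        vals = list(maps.values())
        for v in vals[1:]:
            assert np.allclose(v, vals[0])


class TestTsnr:
    def test_constant_row_flagged_invalid(self):
        t, valid = tsnr_map(ts([[5.0, 5.0, 5.0]]))
        assert not valid[0] and np.isinf(t[0])

    def test_closed_form(self):
        t, valid = tsnr_map(ts([[9.0, 11.0]]))
        assert valid[0]
        assert t[0] == pytest.approx(10 / np.sqrt(2))

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((3, 20)) + 5
        t1, _ = tsnr_map(ts(x))
        t2, _ = tsnr_map(ts(3.7 * x))
        assert np.allclose(t1, t2)


def test_flatmap_smoothing_preserves_constants_and_reduces_variance(rng):
    grid = make_flatmap_grid(8, 8)
    x = ts(rng.standard_normal((64, 5)), "hippocampal-vertex")
    const = ts(np.ones((64, 5)), "hippocampal-vertex")
    sm = smooth_flatmap_timeseries(x, grid, sigma=1.5)
    assert sm.values.var() < x.values.var()
    assert np.allclose(smooth_flatmap_timeseries(const, grid, 1.5).values, 1.0)
    assert smooth_flatmap_timeseries(x, grid, 0.0) is x
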