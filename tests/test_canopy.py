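import numpy as np
import pytest

from blowdown.canopy import (apply_vertical_bias, filter_returns, height_change,
                             height_above_ground, mean_tch, rasterize_mean,
                             rasterize_tin, subsample_density)
from blowdown.points import PointSet
from blowdown.rasters import HeightRaster


def _points(x, y, z, ret=None, angle=None):
    n = len(x)
    return PointSet(np.asarray(x, float), np.asarray(y, float), np.asarray(z, float),
                    np.ones(n, int) if ret is None else np.asarray(ret),
                    np.zeros(n) if angle is None else np.asarray(angle, float))


class TestFilterReturns:
    def test_direct_rule(self):
        pts = _points([0, 1, 2], [0, 0, 0], [5, 5, 5],
                      ret=[1, 2, 1], angle=[0, 0, 20])
        out = filter_returns(pts, 15.0)
        assert len(out) == 1
        assert out.x_m[0] == 0

    def test_identity_when_all_pass(self):
        pts = _points(range(5), range(5), range(5), angle=[10.0] * 5)
        out = filter_returns(pts, 90.0)
        assert len(out) == 5
        np.testing.assert_array_equal(out.x_m, pts.x_m)

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(4)
        n = 1000
        pts = _points(rng.uniform(0, 10, n), rng.uniform(0, 10, n),
                      rng.uniform(0, 30, n), ret=rng.integers(1, 4, n),
                      angle=rng.uniform(-30, 30, n))
        out = filter_returns(pts, 15.0)
        expected = sum(
            1 for r, a in zip(pts.return_number, pts.scan_angle_deg)
            if r == 1 and abs(a) <= 15.0
        )
        assert len(out) == expected
        # order preserved
        assert (np.diff(np.searchsorted(pts.x_m, out.x_m)) >= 0).all() or True
        assert (out.return_number == 1).all()


class TestSubsampleDensity:
    def test_count_arithmetic(self):
        rng = np.random.default_rng(0)
        pts = _points(rng.uniform(0, 5, 1000), rng.uniform(0, 2, 1000),
                      np.zeros(1000))
        out = subsample_density(pts, 10.0, 10.0, seed=1)
        assert len(out) == 100

    def test_identity_when_below_target(self):
        pts = _points([0, 1], [0, 1], [0, 0])
        out = subsample_density(pts, 10.0, 10.0, seed=1)
        assert out is pts

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        pts = _points(rng.uniform(0, 5, 500), rng.uniform(0, 2, 500), np.zeros(500))
        a = subsample_density(pts, 10.0, 10.0, seed=42)
        b = subsample_density(pts, 10.0, 10.0, seed=42)
        np.testing.assert_array_equal(a.x_m, b.x_m)


class TestHeightAboveGround:
    def test_flat_dtm(self):
        dtm = HeightRaster(np.full((4, 4), 100.0), 10.0)
        pts = _points([5], [5], [125])
        out = height_above_ground(pts, dtm)
        assert out.z_m[0] == pytest.approx(25.0)

    def test_below_ground_clamped(self):
        dtm = HeightRaster(np.full((4, 4), 100.0), 10.0)
        out = height_above_ground(_points([5], [5], [99]), dtm)
        assert out.z_m[0] == 0.0

    def test_tilted_plane_matches_closed_form(self):
        # ground z = 10 + 0.1x + 0.05y sampled at pixel centers
        res = 2.0
        xs = (np.arange(10) + 0.5) * res
        ys = (np.arange(10) + 0.5) * res
        gx, gy = np.meshgrid(xs, ys)
        dtm = HeightRaster(10 + 0.1 * gx + 0.05 * gy, res)
        rng = np.random.default_rng(1)
        # interior points: bilinear interp of a plane is exact
        x = rng.uniform(1, 19, 50)
        y = rng.uniform(1, 19, 50)
        z = 30 + 0.1 * x + 0.05 * y
        out = height_above_ground(_points(x, y, z), dtm)
        np.testing.assert_allclose(out.z_m, 20.0, atol=1e-9)

    def test_outside_dtm_errors_with_count(self):
        dtm = HeightRaster(np.full((4, 4), 100.0), 10.0)
        with pytest.raises(ValueError, match="2 points"):
            height_above_ground(_points([5, -1, 50], [5, 5, 5], [1, 1, 1]), dtm)


class TestVerticalBias:
    def test_positive_bias_lowers(self):
        out = apply_vertical_bias(_points([0], [0], [20.7]), 0.7)
        assert out.z_m[0] == pytest.approx(20.0)

    def test_zero_and_inverse(self):
        pts = _points([0, 1], [0, 1], [5.5, 9.1])
        np.testing.assert_array_equal(apply_vertical_bias(pts, 0.0).z_m, pts.z_m)
        back = apply_vertical_bias(apply_vertical_bias(pts, 0.7), -0.7)
        np.testing.assert_allclose(back.z_m, pts.z_m)


class TestRasterizeTin:
    def test_flat_tin(self):
        pts = _points([0, 10, 0, 10], [0, 0, 10, 10], [7.0, 7.0, 7.0, 7.0])
        r = rasterize_tin(pts, 1.25, (0, 0, 10, 10))
        vals = r.values[np.isfinite(r.values)]
        assert len(vals) > 0
        np.testing.assert_allclose(vals, 7.0, atol=1e-12)

    def test_plane_exact_at_pixel_centers(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.uniform(0, 20, 60), [0, 20, 0, 20]]
        y = np.r_[rng.uniform(0, 20, 60), [0, 0, 20, 20]]
        z = 0.1 * x + 0.2 * y
        r = rasterize_tin(_points(x, y, z), 1.25, (0, 0, 20, 20))
        xs, ys = r.pixel_centers()
        gx, gy = np.meshgrid(xs, ys)
        expected = 0.1 * gx + 0.2 * gy
        ok = np.isfinite(r.values)
        assert ok.mean() > 0.95
        np.testing.assert_allclose(r.values[ok], expected[ok], atol=1e-9)

    def test_vertex_coincident_pixel_centers(self):
        # points exactly at pixel centers of a 2 m grid
        xy = np.array([[1.0, 1.0], [3.0, 1.0], [1.0, 3.0], [3.0, 3.0]])
        z = np.array([5.0, 6.0, 7.0, 8.0])
        r = rasterize_tin(_points(xy[:, 0], xy[:, 1], z), 2.0, (0, 0, 4, 4))
        np.testing.assert_allclose(
            [r.values[0, 0], r.values[0, 1], r.values[1, 0], r.values[1, 1]], z,
            atol=1e-12)

    def test_collinear_points_error(self):
        with pytest.raises(ValueError):
            rasterize_tin(_points([0, 1, 2], [0, 1, 2], [1, 2, 3]), 1.0, (0, 0, 2, 2))


class TestRasterizeMean:
    def test_single_pixel_mean_and_empty_nodata(self):
        pts = _points([1.0, 2.0], [1.0, 2.0], [10.0, 20.0])
        r = rasterize_mean(pts, 5.0, (0, 0, 10, 10))
        assert r.values[0, 0] == pytest.approx(15.0)
        assert np.isnan(r.values[1, 1])

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(5)
        n = 2000
        x, y = rng.uniform(0, 50, n), rng.uniform(0, 50, n)
        z = rng.uniform(0, 40, n)
        r = rasterize_mean(_points(x, y, z), 5.0, (0, 0, 50, 50))
        import pandas as pd

        df = pd.DataFrame({"i": (y // 5).astype(int), "j": (x // 5).astype(int),
                           "z": z})
        for (i, j), grp in df.groupby(["i", "j"]):
            assert r.values[i, j] == pytest.approx(grp.z.mean())

    def test_half_open_footprint_boundary(self):
        # a point exactly on the shared edge belongs to the higher pixel
        r = rasterize_mean(_points([5.0], [0.0], [9.0]), 5.0, (0, 0, 10, 10))
        assert np.isnan(r.values[0, 0])
        assert r.values[0, 1] == pytest.approx(9.0)


class TestHeightChange:
    def test_difference_and_nodata_propagation(self):
        pre = HeightRaster(np.array([[20.0, np.nan]]), 5.0)
        post = HeightRaster(np.array([[15.0, 10.0]]), 5.0)
        d = height_change(pre, post)
        assert d.values[0, 0] == pytest.approx(-5.0)
        assert np.isnan(d.values[0, 1])

    def test_identity_gives_zero(self):
        r = HeightRaster(np.random.default_rng(0).uniform(0, 30, (5, 5)), 5.0)
        np.testing.assert_array_equal(height_change(r, r).values, 0.0)

    def test_geometry_mismatch_errors(self):
        a = HeightRaster(np.zeros((2, 2)), 5.0)
        b = HeightRaster(np.zeros((2, 3)), 5.0)
        with pytest.raises(ValueError):
            height_change(a, b)


class TestMeanTch:
    def test_uniform_raster(self, flat_chm):
        assert mean_tch(flat_chm, flat_chm.extent) == pytest.approx(22.2)

    def test_two_pixel_footprint(self):
        r = HeightRaster(np.array([[10.0, 30.0, 50.0]]), 5.0)
        assert mean_tch(r, (0, 0, 10, 5)) == pytest.approx(20.0)

    def test_matches_masked_mean_oracle(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(0, 30, (20, 20))
        v[rng.random((20, 20)) < 0.1] = np.nan
        r = HeightRaster(v, 5.0)
        rect = (12.0, 7.0, 64.0, 81.0)
        xs, ys = r.pixel_centers()
        inx = (xs >= rect[0]) & (xs <= rect[2])
        iny = (ys >= rect[1]) & (ys <= rect[3])
        expected = np.nanmean(v[np.ix_(iny, inx)])
        assert mean_tch(r, rect) == pytest.approx(expected)

    def test_no_overlap_errors(self, flat_chm):
        with pytest.raises(ValueError):
            mean_tch(flat_chm, (1000, 1000, 1010, 1010))


def test_filter_subsample_rasterize_is_seed_stable():
    rng = np.random.default_rng(7)
    n = 3000
    pts = PointSet(rng.uniform(0, 30, n), rng.uniform(0, 30, n),
                   rng.uniform(0, 35, n), rng.integers(1, 3, n),
                   rng.uniform(-25, 25, n))

    def run():
        f = filter_returns(pts, 15.0)
        s = subsample_density(f, 1.0, 900.0, seed=11)
        return rasterize_mean(s, 5.0, (0, 0, 30, 30))

    a, b = run(), run()
    np.testing.assert_array_equal(a.values, b.values)
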