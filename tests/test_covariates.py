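import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsfkit import covariates as cov
from rsfkit.raster import RasterGrid


def grid_of(vals, cell=30.0):
    return RasterGrid(np.asarray(vals, dtype=float), origin=(cell / 2, cell / 2),
                      cell_size=cell)


# ---------------------------------------------------------------------------
# terrain metrics
# ---------------------------------------------------------------------------

class TestTRI:
    def test_flat_dem_is_zero(self):
        tri = cov.compute_tri(grid_of(np.full((4, 4), 5.0)))
        assert np.allclose(tri.values, 0.0)

    def test_center_spike_equals_sqrt8(self):
        dem = np.zeros((3, 3))
        dem[1, 1] = 1.0
        tri = cov.compute_tri(grid_of(dem))
        assert tri.values[1, 1] == pytest.approx(np.sqrt(8.0))

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        dem = rng.random((6, 6)) * 50
        t1 = cov.compute_tri(grid_of(dem))
        t2 = cov.compute_tri(grid_of(dem + 100.0))
        assert np.allclose(t1.values, t2.values)

    def test_matches_bruteforce_with_edge_neighbours(self):
        rng = np.random.default_rng(1)
        dem = rng.random((8, 7)) * 10
        tri = cov.compute_tri(grid_of(dem)).values
        for i in range(8):
            for j in range(7):
                ssq = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        if 0 <= i + di < 8 and 0 <= j + dj < 7:
                            ssq += (dem[i + di, j + dj] - dem[i, j]) ** 2
                assert tri[i, j] == pytest.approx(np.sqrt(ssq))

    def test_rejects_tiny_dem(self):
        with pytest.raises(ValueError):
            cov.compute_tri(grid_of(np.zeros((2, 2))))


class TestSlopeAspect:
    def test_flat_slope_zero_northness_zero(self):
        dem = grid_of(np.full((5, 5), 3.0))
        assert np.allclose(cov.compute_slope(dem).values, 0.0)
        assert np.allclose(cov.compute_aspect_northness(dem).values, 0.0)

    def test_unit_gradient_gives_45_degrees(self):
        # rises 30 m per 30-m cell eastward
        dem = grid_of(np.tile(np.arange(5) * 30.0, (5, 1)))
        slope = cov.compute_slope(dem)
        assert slope.values[2, 2] == pytest.approx(45.0)

    def test_northness_sign_follows_downslope_direction(self):
        # row 0 is north; values increasing with row index = higher in south
        south_high = grid_of(np.tile(np.arange(5)[:, None] * 10.0, (1, 5)))
        assert cov.compute_aspect_northness(south_high).values[2, 2] == \
            pytest.approx(1.0)  # downslope faces north
        north_high = grid_of(np.tile(np.arange(5)[::-1, None] * 10.0, (1, 5)))
        assert cov.compute_aspect_northness(north_high).values[2, 2] == \
            pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# focal mean
# ---------------------------------------------------------------------------

class TestFocalMean:
    def test_constant_grid_preserved(self):
        g = grid_of(np.full((10, 10), 7.5))
        out = cov.focal_mean(g, 331.0)
        assert np.allclose(out.values, 7.5)

    def test_radius_below_cell_size_is_identity(self):
        rng = np.random.default_rng(2)
        g = grid_of(rng.random((6, 6)))
        out = cov.focal_mean(g, 10.0)
        assert np.allclose(out.values, g.values)

    def test_plus_window_single_spike(self):
        # radius covering exactly 5 cell centres (the + shape): 30 < r < 30*sqrt(2)
        vals = np.zeros((7, 7))
        vals[3, 3] = 1.0
        out = cov.focal_mean(grid_of(vals), 35.0)
        assert out.values[3, 3] == pytest.approx(0.2)
        assert out.values[3, 4] == pytest.approx(0.2)
        assert out.values[4, 4] == 0.0

    @pytest.mark.parametrize("radius", [35.0, 60.0, 331.0, 887.0])
    def test_matches_bruteforce_loop(self, radius):
        rng = np.random.default_rng(3)
        vals = rng.random((20, 20))
        vals[4, 5] = np.nan
        g = grid_of(vals)
        out = cov.focal_mean(g, radius).values
        X, Y = g.cell_centers()
        for i in range(0, 20, 3):
            for j in range(0, 20, 3):
                d2 = (X - X[i, j]) ** 2 + (Y - Y[i, j]) ** 2
                member = (d2 <= radius**2) & np.isfinite(vals)
                if np.isnan(vals[i, j]):
                    assert np.isnan(out[i, j])
                else:
                    assert out[i, j] == pytest.approx(vals[member].mean())

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            cov.focal_mean(grid_of(np.zeros((3, 3))), 0.0)


def test_log_ruggedness_examples():
    g = grid_of(np.array([[0.0, np.e - 1.0], [3.0, 7.0]]))
    out = cov.log_ruggedness(g).values
    assert out[0, 0] == 0.0
    assert out[0, 1] == pytest.approx(1.0)
    assert out[1, 0] < out[1, 1]  # monotone
    with pytest.raises(ValueError):
        cov.log_ruggedness(grid_of(-np.ones((2, 2))))


# ---------------------------------------------------------------------------
# distances / decay
# ---------------------------------------------------------------------------

class TestDistanceGrid:
    def test_point_feature_distances(self):
        from shapely.geometry import Point
        g = grid_of(np.zeros((5, 5)))
        out = cov.distance_grid([Point(15.0, 15.0)], g)
        assert out.values[4, 0] == 0.0            # on the feature
        assert out.values[4, 3] == pytest.approx(90.0)  # 3 cells due east
        two = cov.distance_grid([Point(15.0, 15.0), Point(135.0, 15.0)], g)
        assert np.all(two.values <= out.values + 1e-9)  # per-cell minimum

    def test_matches_bruteforce_nearest_geometry(self):
        from shapely.geometry import LineString, Point
        rng = np.random.default_rng(4)
        g = grid_of(np.zeros((15, 15)))
        feats = [Point(rng.uniform(0, 450), rng.uniform(0, 450)),
                 LineString([(0, 0), (450, 450)])]
        out = cov.distance_grid(feats, g).values
        X, Y = g.cell_centers()
        from shapely.geometry import Point as P
        for i in range(0, 15, 4):
            for j in range(0, 15, 4):
                d = min(f.distance(P(X[i, j], Y[i, j])) for f in feats)
                assert out[i, j] == pytest.approx(d)

    def test_rejects_empty_feature_set(self):
        with pytest.raises(ValueError):
            cov.distance_grid([], grid_of(np.zeros((3, 3))))


def test_alpha_rule_caps_at_6400():
    assert cov.compute_alpha([8200.0]).alpha == 6400.0
    assert cov.compute_alpha([1000.0, 3000.0]).alpha == 2000.0
    assert cov.compute_alpha([6400.0, 6400.0]).alpha == 6400.0
    with pytest.raises(ValueError):
        cov.compute_alpha([100.0, -1.0])


def test_decay_transform_examples():
    a = 500.0
    assert cov.decay_transform(0.0, a) == 1.0
    assert cov.decay_transform(a, a) == pytest.approx(np.exp(-1))
    assert cov.decay_transform(2 * a, a) == pytest.approx(np.exp(-2))
    with pytest.raises(ValueError):
        cov.decay_transform(np.array([-1.0]), a)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(0.0, 2e4), min_size=2, max_size=30),
       st.floats(100.0, 6400.0))
def test_decay_is_bounded_and_monotone(dists, alpha):
    d = np.sort(np.asarray(dists))
    out = cov.decay_transform(d, alpha)
    assert np.all(out > 0) and np.all(out <= 1.0)
    assert np.all(np.diff(out) <= 1e-15)


# ---------------------------------------------------------------------------
# standardization / screening / radii
# ---------------------------------------------------------------------------

class TestStandardize:
    def test_hand_example_sample_sd(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, rec = cov.standardize(df)
        assert np.allclose(out["a"], [-1.0, 0.0, 1.0])
        assert rec.sds["a"] == pytest.approx(1.0)

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.standard_normal(50)})
        once, _ = cov.standardize(df)
        twice, _ = cov.standardize(once)
        assert np.allclose(once["a"], twice["a"], atol=1e-12)

    def test_reference_rows_freeze_moments(self):
        df = pd.DataFrame({"a": [0.0, 2.0, 4.0, 100.0]})
        ref = np.array([True, True, True, False])
        out, rec = cov.standardize(df, reference=ref)
        assert out["a"].iloc[1] == 0.0  # equals the training mean
        assert abs(out["a"][:3].mean()) < 1e-10
        assert out["a"][:3].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_rejected_by_name(self):
        df = pd.DataFrame({"good": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            cov.standardize(df)


class TestCorrelationScreen:
    def test_duplicate_column_drops_one(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(100)
        df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.standard_normal(100)})
        kept = cov.correlation_screen(df)
        assert sorted(kept) == ["a", "c"]

    def test_orthogonal_columns_all_retained(self):
        df = pd.DataFrame(np.eye(4), columns=list("wxyz"))
        assert cov.correlation_screen(df) == list("wxyz")

    def test_slope_dropped_in_favour_of_ruggedness_on_rough_terrain(self):
        # slope and TRI are strongly collinear on rough synthetic DEMs
        from rsfkit.covariates import compute_slope, compute_tri
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(7)
        dem = grid_of(gaussian_filter(rng.standard_normal((40, 40)), 2.0) * 300)
        tri = compute_tri(dem).values.ravel()
        slope = compute_slope(dem).values.ravel()
        elev = dem.values.ravel()
        df = pd.DataFrame({"tri": tri, "elevation": elev, "slope": slope})
        assert abs(np.corrcoef(tri, slope)[0, 1]) > 0.7
        kept = cov.correlation_screen(df, priority=["tri", "elevation"])
        assert "slope" not in kept
        assert {"tri", "elevation"} <= set(kept)


class TestCandidateRadii:
    def test_hand_arithmetic_with_summer_half_max(self):
        steps = {"a": [100.0, 200.0, 300.0], "b": [50.0, 150.0, 250.0]}
        res = cov.compute_candidate_radii(steps, season="summer")
        assert res.radii == (75.0, 138.0, 175.0, 275.0)

    def test_half_up_rounding_reproduces_1503(self):
        steps = {"a": [10.0, 1000.0, 3005.0]}
        res = cov.compute_candidate_radii(steps, season="summer")
        assert 1503.0 in res.radii

    def test_single_individual_uses_own_min_mean_max(self):
        res = cov.compute_candidate_radii({"a": [60.0, 331.0, 602.0]},
                                          season="nest")
        assert res.radii == (60.0, 331.0, 602.0)

    def test_empty_individual_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            res = cov.compute_candidate_radii(
                {"a": [100.0], "b": []}, season="nest")
        assert res.radii == (100.0,)


def test_scale_candidates_must_increase():
    with pytest.raises(ValueError):
        cov.ScaleCandidateSet("shrub", (60.0, 60.0, 887.0))
    with pytest.raises(ValueError):
        cov.DecayParams("road", 0.0)
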