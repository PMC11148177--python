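"""NDVI computation, compositing, semivariogram estimation and spherical fit."""

import math

import numpy as np
import pytest

import fluxfoot as ff
from fluxfoot.heterogeneity import DIRECTIONS, spherical_model
from fluxfoot.rasters import ContinuousRaster, GridSpec


def raster(values, cell=10.0):
    values = np.asarray(values, dtype=float)
    grid = GridSpec(cell_size=cell, half_width=cell * values.shape[0] / 2.0)
    return ContinuousRaster(grid, values)


class TestNdvi:
    def test_band_arithmetic(self):
        out = ff.compute_ndvi(raster([[0.5, 0.3], [0.3, 0.3]]),
                              raster([[0.1, 0.3], [0.3, 0.3]]))
        assert out.values[0, 0] == pytest.approx((0.5 - 0.1) / (0.5 + 0.1))
        assert out.values[0, 1] == 0.0

    def test_zero_denominator_masked(self):
        out = ff.compute_ndvi(raster([[0.0, 0.5], [0.5, 0.5]]),
                              raster([[0.0, 0.1], [0.1, 0.1]]))
        assert not out.mask[0, 0] and out.mask[0, 1]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="co-registered"):
            ff.compute_ndvi(raster(np.zeros((2, 2))), raster(np.zeros((3, 3))))


class TestAnnualComposite:
    def test_single_clean_scene_is_identity(self):
        scene = raster([[0.2, 0.4], [0.4, 0.2]])
        out = ff.annual_composite([(scene, 1.0)])
        assert np.array_equal(out.values, scene.values)

    def test_cellwise_mean(self):
        out = ff.annual_composite([(raster(np.full((2, 2), 0.2)), 0.0),
                                   (raster(np.full((2, 2), 0.4)), 2.0)])
        assert np.allclose(out.values, 0.3)

    def test_cloud_filter_is_strict(self):
        clean = raster(np.full((2, 2), 0.2))
        cloudy = raster(np.full((2, 2), 0.8))
        out = ff.annual_composite([(clean, 4.99), (cloudy, 5.0)])
        assert np.allclose(out.values, 0.2)  # the 5.0% scene is dropped

    def test_all_dropped_is_an_error(self):
        with pytest.raises(ValueError, match="cloud"):
            ff.annual_composite([(raster(np.zeros((2, 2))), 80.0)])


def brute_force_variogram(values, mask, cell, direction, weights=None,
                          max_cells=None):
    """Naive all-pairs estimator with the same binning/sector conventions."""
    n = values.shape[0]
    if max_cells is None:
        max_cells = n
    num, den, cnt = {}, {}, {}
    for i1 in range(n):
        for j1 in range(values.shape[1]):
            if not mask[i1, j1]:
                continue
            for i2 in range(n):
                for j2 in range(values.shape[1]):
                    if not mask[i2, j2]:
                        continue
                    di, dj = i2 - i1, j2 - j1
                    if dj < 0 or (dj == 0 and di <= 0):
                        continue  # count each unordered pair once
                    b = round(math.hypot(di, dj))
                    if b == 0 or b > max_cells:
                        continue
                    if direction != "omni":
                        az = math.degrees(math.atan2(dj, di * -1.0)) % 180.0
                        centre = DIRECTIONS[direction]
                        lo, hi = centre - 22.5, centre + 22.5
                        inside = (az >= lo % 180.0 or az < hi) if centre == 0.0 \
                            else (lo <= az < hi)
                        if not inside:
                            continue
                    d2 = (values[i1, j1] - values[i2, j2]) ** 2
                    w = 1.0 if weights is None else weights[i1, j1] * weights[i2, j2]
                    num[b] = num.get(b, 0.0) + w * d2
                    den[b] = den.get(b, 0.0) + w
                    cnt[b] = cnt.get(b, 0) + 1
    return {b: 0.5 * num[b] / den[b] for b in num}, cnt


class TestDirectionalSemivariogram:
    def test_constant_field_has_zero_semivariance(self):
        est = ff.directional_semivariogram(np.full((5, 5), 0.7),
                                           np.ones((5, 5), bool), 10.0, "omni")
        assert np.all(est.gamma[est.counts > 0] == 0.0)

    def test_alternating_transect_by_hand(self):
        # pairs at one lag: (0,1), (1,0), (0,1) -> mean squared diff 1, γ = 0.5
        values = np.array([[0.0, 1.0, 0.0, 1.0]])
        est = ff.directional_semivariogram(values, np.ones((1, 4), bool),
                                           1.0, "EW")
        assert est.gamma[0] == pytest.approx(0.5)
        assert est.counts[0] == 3

    @pytest.mark.parametrize("direction", ["EW", "NS", "NE-SW", "NW-SE", "omni"])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_all_pairs_enumeration(self, direction, weighted):
        rng = np.random.default_rng(42)
        values = rng.random((5, 5))
        mask = rng.random((5, 5)) > 0.15
        weights = rng.random((5, 5)) if weighted else None
        est = ff.directional_semivariogram(values, mask, 10.0, direction,
                                           weights=weights, max_lag_m=50.0)
        oracle, counts = brute_force_variogram(values, mask, 10.0, direction,
                                               weights=weights, max_cells=5)
        for k, lag_cells in enumerate(np.round(est.lags / 10.0).astype(int)):
            if est.counts[k] == 0:
                assert lag_cells not in counts
                continue
            assert est.counts[k] == counts[lag_cells]
            assert est.gamma[k] == pytest.approx(oracle[lag_cells], abs=1e-12)

    def test_invariant_to_additive_constant_and_quadratic_in_scale(self):
        rng = np.random.default_rng(3)
        values = rng.random((8, 8))
        mask = np.ones((8, 8), bool)
        base = ff.directional_semivariogram(values, mask, 10.0, "omni")
        shifted = ff.directional_semivariogram(values + 3.7, mask, 10.0, "omni")
        scaled = ff.directional_semivariogram(values * 2.0, mask, 10.0, "omni")
        ok = base.counts > 0
        assert np.allclose(base.gamma[ok], shifted.gamma[ok])
        assert np.allclose(4.0 * base.gamma[ok], scaled.gamma[ok])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="2 unmasked"):
            ff.directional_semivariogram(np.ones((3, 3)),
                                         np.eye(3, dtype=bool)[:1].repeat(3, 0) * False,
                                         10.0, "omni")


class TestOmnidirectional:
    def _est(self, gamma, counts=None):
        gamma = np.asarray(gamma, dtype=float)
        counts = np.ones_like(gamma, dtype=int) if counts is None else counts
        return ff.VariogramEstimate("EW", np.arange(1, len(gamma) + 1) * 10.0,
                                    gamma, counts)

    def test_mean_of_identical_inputs_is_identity(self):
        e = self._est([0.1, 0.2, 0.3])
        out = ff.omnidirectional([e, e, e, e])
        assert np.allclose(out.gamma, e.gamma)

    def test_per_lag_arithmetic_mean(self):
        ests = [self._est([g]) for g in (1.0, 2.0, 3.0, 4.0)]
        assert ff.omnidirectional(ests).gamma[0] == pytest.approx(2.5)

    def test_mismatched_lags_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            ff.omnidirectional([self._est([0.1, 0.2]), self._est([0.1])])


class TestSphericalFit:
    def test_exact_model_recovery(self):
        lags = np.arange(10.0, 500.0, 10.0)
        gamma = spherical_model(lags, 2e-4, 1e-3, 240.0)
        est = ff.VariogramEstimate("omni", lags, gamma,
                                   np.full(len(lags), 100, dtype=int))
        fit = ff.fit_spherical(est)
        assert fit.nugget == pytest.approx(2e-4, abs=1e-6)
        assert fit.sill == pytest.approx(1e-3, abs=1e-6)
        assert fit.range_m == pytest.approx(240.0, abs=1e-2)
        assert fit.nugget_sill_ratio == pytest.approx(20.0, abs=0.1)

    def test_flat_variogram_is_pure_nugget(self):
        lags = np.arange(10.0, 100.0, 10.0)
        est = ff.VariogramEstimate("omni", lags, np.full(len(lags), 0.05),
                                   np.full(len(lags), 10, dtype=int))
        fit = ff.fit_spherical(est)
        assert fit.degenerate
        assert fit.nugget == pytest.approx(0.05, rel=1e-3)
        assert fit.sill == pytest.approx(0.05, rel=1e-3)
        assert fit.nugget_sill_ratio == pytest.approx(100.0, abs=0.1)

    def test_simulated_field_recovery(self):
        cfg = ff.SceneConfig(seed=3, raster_extent=2000.0, cell_sizes=(50.0, 10.0),
                             variogram_truth=(2e-4, 1e-3, 240.0))
        field = ff.gen_ndvi_field(cfg)
        est = ff.directional_semivariogram(field.values,
                                           np.ones_like(field.values, bool),
                                           10.0, "omni", max_lag_m=400.0)
        fit = ff.fit_spherical(est)
        assert fit.range_m == pytest.approx(240.0, rel=0.20)
        assert fit.sill == pytest.approx(1e-3, rel=0.25)
        assert 0.0 <= fit.nugget_sill_ratio <= 100.0

    def test_too_few_lags_rejected(self):
        est = ff.VariogramEstimate("omni", np.array([10.0, 20.0, 30.0]),
                                   np.array([0.1, 0.2, 0.3]),
                                   np.array([5, 5, 5]))
        with pytest.raises(ValueError, match="4 lags"):
            ff.fit_spherical(est)
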