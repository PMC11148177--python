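"""Statistical structure of the synthetic scene generators."""

import numpy as np
import pytest

import fluxfoot as ff
from fluxfoot.heterogeneity import spherical_model
from fluxfoot.synthetic import spherical_covariance


class TestSceneConfigValidation:
    def test_wind_rose_must_normalize(self):
        with pytest.raises(ValueError, match="wind rose"):
            ff.SceneConfig(wind_rose=((0.0, 0.5), (90.0, 0.4)))

    def test_stability_mix_must_normalize(self):
        with pytest.raises(ValueError, match="stability"):
            ff.SceneConfig(stability_mix=(0.5, 0.5, 0.5))

    def test_variogram_truth_ordering(self):
        with pytest.raises(ValueError, match="variogram"):
            ff.SceneConfig(variogram_truth=(0.01, 0.001, 240.0))

    def test_cell_must_divide_extent(self):
        with pytest.raises(ValueError, match="divide"):
            ff.SceneConfig(raster_extent=2000.0, cell_sizes=(30.0, 10.0))

    def test_unknown_landcover_code(self):
        with pytest.raises(ValueError, match="999"):
            ff.SceneConfig(landcover_patches=((999, {"shape": "all"}),))


class TestMetSeries:
    def test_seed_determinism(self):
        cfg = ff.SceneConfig(seed=1, n_halfhours=1000)
        assert ff.gen_met_series(cfg) == ff.gen_met_series(cfg)

    def test_distinct_seeds_differ(self):
        a = ff.gen_met_series(ff.SceneConfig(seed=1, n_halfhours=50))
        b = ff.gen_met_series(ff.SceneConfig(seed=2, n_halfhours=50))
        assert a != b

    @pytest.mark.parametrize("mix,sign", [((1, 0, 0), -1), ((0, 0, 1), 1)])
    def test_stability_regime_sets_obukhov_sign(self, mix, sign):
        recs = ff.gen_met_series(ff.SceneConfig(seed=3, n_halfhours=200,
                                                stability_mix=mix))
        assert all(np.sign(r.L) == sign for r in recs)

    def test_regime_fractions_match_mix(self):
        mix = (0.5, 0.0, 0.5)
        recs = ff.gen_met_series(ff.SceneConfig(seed=4, n_halfhours=2000,
                                                stability_mix=mix))
        frac_unstable = np.mean([r.L < 0 for r in recs])
        # binomial 3-sigma band around 0.5 at n=2000
        assert abs(frac_unstable - 0.5) < 3 * 0.5 / np.sqrt(2000)

    def test_concentrated_rose_sets_circular_mean(self):
        recs = ff.gen_met_series(ff.SceneConfig(seed=5, n_halfhours=1000,
                                                wind_rose=((90.0, 1.0),)))
        wd = np.radians([r.wd for r in recs])
        mean_deg = np.degrees(np.angle(np.exp(1j * wd).mean())) % 360.0
        assert abs(mean_deg - 90.0) < 5.0

    def test_driver_ranges(self):
        recs = ff.gen_met_series(ff.SceneConfig(seed=6, n_halfhours=500))
        assert all(r.ws > 0 and 0 <= r.wd < 360 for r in recs)
        assert all(0.05 <= r.ustar <= 1.5 for r in recs)
        # sensible heat flux consistent with the drawn Obukhov length
        assert all(np.sign(r.h) == -np.sign(r.L) for r in recs)


class TestLandcoverRaster:
    def test_single_patch_uniform(self):
        cfg = ff.SceneConfig(landcover_patches=((130, {"shape": "all"}),))
        raster = ff.gen_landcover_raster(cfg)
        assert np.all(raster.codes == 130)

    def test_halfplane_split_is_even(self):
        cfg = ff.SceneConfig(landcover_patches=(
            (130, {"shape": "all"}),
            (70, {"shape": "halfplane", "bearing": 90.0, "offset": 0.0}),
        ))
        raster = ff.gen_landcover_raster(cfg)
        frac = np.mean(raster.codes == 70)
        n = raster.grid.n
        assert abs(frac - 0.5) <= 1.0 / n  # within one cell column

    def test_disc_patch_area(self):
        r = 600.0
        cfg = ff.SceneConfig(landcover_patches=(
            (130, {"shape": "all"}),
            (60, {"shape": "disc", "cx": 0.0, "cy": 0.0, "r": r}),
        ))
        raster = ff.gen_landcover_raster(cfg)
        cell = raster.grid.cell_size
        area = np.sum(raster.codes == 60) * cell**2
        ring = 2 * np.pi * r * cell  # one cell ring of tolerance
        assert abs(area - np.pi * r**2) <= ring

    def test_patch_outside_extent_rejected(self):
        cfg = ff.SceneConfig(landcover_patches=(
            (130, {"shape": "all"}),
            (60, {"shape": "disc", "cx": 1900.0, "cy": 0.0, "r": 500.0}),
        ))
        with pytest.raises(ValueError, match="outside"):
            ff.gen_landcover_raster(cfg)

    def test_seed_determinism(self):
        cfg = ff.SceneConfig(seed=9)
        assert np.array_equal(ff.gen_landcover_raster(cfg).codes,
                              ff.gen_landcover_raster(cfg).codes)


class TestNdviField:
    def test_zero_sill_gives_constant_field(self):
        cfg = ff.SceneConfig(variogram_truth=(0.0, 0.0, 240.0))
        raster = ff.gen_ndvi_field(cfg)
        assert np.ptp(raster.values) == 0.0

    def test_seed_determinism_and_variance(self):
        cfg = ff.SceneConfig(seed=3)
        a = ff.gen_ndvi_field(cfg)
        b = ff.gen_ndvi_field(cfg)
        assert np.array_equal(a.values, b.values)
        # sample variance close to the configured sill
        assert a.values.var() == pytest.approx(1e-3, rel=0.15)
        assert np.all(np.abs(a.values) <= 1.0)

    def test_empirical_variogram_follows_spherical_truth(self):
        # 400x400 cells at 10 m; truth echoes a realistic NDVI structure
        cfg = ff.SceneConfig(seed=3, raster_extent=2000.0, cell_sizes=(50.0, 10.0),
                             variogram_truth=(2e-4, 1e-3, 240.0))
        raster = ff.gen_ndvi_field(cfg)
        est = ff.directional_semivariogram(
            raster.values, np.ones_like(raster.values, bool), 10.0, "omni",
            max_lag_m=240.0)
        truth = spherical_model(est.lags, 2e-4, 1e-3, 240.0)
        ok = est.counts > 0
        assert np.all(np.abs(est.gamma[ok] - truth[ok]) <= 0.20 * truth[ok])

    def test_repeat_simulation_recovers_range(self):
        fits = []
        for seed in (3, 4):
            cfg = ff.SceneConfig(seed=seed, raster_extent=2000.0,
                                 cell_sizes=(50.0, 10.0))
            raster = ff.gen_ndvi_field(cfg)
            est = ff.directional_semivariogram(
                raster.values, np.ones_like(raster.values, bool), 10.0, "omni",
                max_lag_m=400.0)
            fits.append(ff.fit_spherical(est))
        for fit in fits:
            assert fit.range_m == pytest.approx(240.0, rel=0.20)
        assert fits[0].sill != fits[1].sill  # genuinely distinct fields

    def test_covariance_kernel_shape(self):
        h = np.array([0.0, 120.0, 240.0, 500.0])
        c = spherical_covariance(h, 8e-4, 240.0)
        assert c[0] == pytest.approx(8e-4)
        assert c[2] == 0.0 and c[3] == 0.0
        assert np.all(np.diff(c) <= 0)


class TestSigmaVTraining:
    def test_attainable_r2_matches_request(self):
        _, attainable = ff.gen_sigma_v_training(ff.SceneConfig(seed=5),
                                                n=5000, target_r2=0.78)
        assert attainable == pytest.approx(0.78, abs=1e-9)

    def test_zero_noise_attainable_is_one(self):
        _, attainable = ff.gen_sigma_v_training(ff.SceneConfig(seed=5),
                                                n=2000, noise_sd=0.0)
        assert attainable == 1.0

    def test_seed_determinism(self):
        cfg = ff.SceneConfig(seed=8)
        a, _ = ff.gen_sigma_v_training(cfg, n=1500)
        b, _ = ff.gen_sigma_v_training(cfg, n=1500)
        assert a.equals(b)
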