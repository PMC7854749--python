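import numpy as np
import pandas as pd
import pytest

from conftest import series_arrays
from s2cropmap import synthetic as syn
from s2cropmap.features import (
    ANNUAL_STATS,
    DEFAULT_WINDOWS,
    StageWindows,
    annual_metrics,
    bank_manifest,
    build_bank,
    build_crop_bank,
    build_cropland_bank,
    crop_feature_names,
    cropland_feature_names,
    fit_harmonics,
    harmonic_design,
    seasonal_metrics,
    temporal_composites,
)
from s2cropmap.spectral import BAND_INDEX, PROXIES, compute_index
from s2cropmap.temporal import GRID_STARTS


class TestBankStructure:
    def test_cropland_bank_is_184(self):
        names = cropland_feature_names()
        assert len(names) == 184
        assert len(set(names)) == 184

    def test_crop_bank_is_255(self):
        names = crop_feature_names()
        assert len(names) == 255
        assert len(set(names)) == 255

    def test_cropland_group_decomposition(self):
        m = bank_manifest("cropland")
        counts = m["group"].value_counts()
        assert counts["seasonal"] == 30
        assert counts["annual"] == 100
        assert counts["texture"] == 54

    def test_crop_group_decomposition(self):
        m = bank_manifest("crop")
        counts = m["group"].value_counts()
        assert counts["timeseries"] == 220
        assert counts["composite"] == 20
        assert counts["harmonic"] == 15

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown bank mode"):
            bank_manifest("forest")


class TestStageWindows:
    def test_printed_windows(self):
        w = StageWindows()
        assert w.seeding == (109, 169)
        assert w.growth == (170, 230)
        assert w.harvest == (231, 291)
        assert w.season == (90, 300)

    def test_stages_inside_season(self):
        w = StageWindows()
        for s in ("seeding", "growth", "harvest"):
            lo, hi = w.window(s)
            assert w.season[0] <= lo < hi <= w.season[1]

    def test_interval_masks_partition(self):
        w = StageWindows()
        total = sum(w.interval_mask(s).sum() for s in ("seeding", "growth", "harvest"))
        assert total == 19  # starts 110..290 fall in exactly one stage


class TestSeasonalMetrics:
    def test_constant_series(self):
        reg = np.full((10, 22), 0.42)
        out = seasonal_metrics(reg)
        assert len(out) == 30
        assert all(v == pytest.approx(0.42) for v in out.values())

    def test_linear_series_monotone_stages(self):
        reg = np.tile(np.linspace(0, 1, 22), (10, 1))
        out = seasonal_metrics(reg)
        assert out["growth_ndvi_median"] > out["seeding_ndvi_median"]
        assert out["harvest_ndvi_median"] > out["growth_ndvi_median"]

    def test_step_series(self):
        step = (GRID_STARTS >= 170).astype(float)
        reg = np.tile(step, (10, 1))
        out = seasonal_metrics(reg)
        assert out["seeding_ndvi_median"] == 0.0
        assert out["growth_ndvi_median"] == 1.0


class TestAnnualMetrics:
    def test_constant_series(self):
        out = annual_metrics(np.full((10, 22), 0.3))
        for p in PROXIES:
            assert out[f"annual_{p}_std"] == pytest.approx(0.0, abs=1e-12)
            assert out[f"annual_{p}_amplitude"] == 0.0
            for s in ("min", "max", "mean", "p5", "p50", "p95"):
                assert out[f"annual_{p}_{s}"] == pytest.approx(0.3)

    def test_order_statistics(self):
        reg = np.tile(np.arange(1.0, 23.0), (10, 1))
        out = annual_metrics(reg)
        assert out["annual_ndvi_amplitude"] == 21.0
        assert out["annual_ndvi_p50"] == 11.5

    def test_percentiles_monotone(self, rng):
        reg = rng.random((10, 22))
        out = annual_metrics(reg)
        for p in PROXIES:
            qs = [out[f"annual_{p}_{s}"] for s in ("p5", "p25", "p50", "p75", "p95")]
            assert qs == sorted(qs)

    def test_count(self, rng):
        assert len(annual_metrics(rng.random((10, 22)))) == 100
        assert len(ANNUAL_STATS) == 10


class TestTemporalComposites:
    def test_single_valid_observation(self, rng):
        refl = rng.random((4, 8)) * 0.5
        valid = np.array([False, True, False, False])
        out = temporal_composites([100, 150, 200, 250], refl, valid)
        for p in PROXIES:
            expect = compute_index(refl[1], p)
            assert out[f"greenest_{p}"] == pytest.approx(expect)
            assert out[f"wettest_{p}"] == pytest.approx(expect)

    def test_greenest_tracks_ndvi_argmax(self):
        doys = np.array([150, 210, 270])
        refl = np.tile(np.linspace(0.1, 0.45, 8), (3, 1))
        refl[1, BAND_INDEX["nir"]] = 0.8   # NDVI peak at DOY 210
        refl[1, BAND_INDEX["re3"]] = 0.5
        out = temporal_composites(doys, refl, np.ones(3, bool))
        assert out["greenest_rep"] == pytest.approx(compute_index(refl[1], "rep"))

    def test_tie_broken_by_earliest_doy(self):
        refl = np.tile(np.linspace(0.1, 0.45, 8), (3, 1))
        refl[2, BAND_INDEX["re2"]] = 0.9  # differs, but same NDVI/LSWI
        out = temporal_composites([100, 140, 180], refl, np.ones(3, bool))
        assert out["greenest_re2"] == pytest.approx(refl[0, BAND_INDEX["re2"]])

    def test_no_valid_observations_error(self):
        with pytest.raises(ValueError, match="no valid"):
            temporal_composites([100], np.full((1, 8), 0.2), np.array([False]))


class TestHarmonics:
    def test_exact_recovery(self):
        doys = np.arange(90, 301, 7)
        true = np.array([0.5, 0.2, -0.1, 0.05, 0.0])
        vals = harmonic_design(doys) @ true
        coef = fit_harmonics(doys, vals)
        np.testing.assert_allclose(coef, true, atol=1e-10)

    def test_constant_series(self):
        doys = np.arange(90, 301, 10)
        coef = fit_harmonics(doys, np.full(len(doys), 0.3))
        assert coef[0] == pytest.approx(0.3, abs=1e-10)
        np.testing.assert_allclose(coef[1:], 0.0, atol=1e-10)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_harmonics([100, 120, 140, 160], [0.1, 0.2, 0.3, 0.4])

    def test_singular_design(self):
        doys = np.full(6, 150)
        with pytest.raises(ValueError, match="singular"):
            fit_harmonics(doys, np.full(6, 0.2))

    def test_t_origin_january_first(self):
        x = harmonic_design([1])
        np.testing.assert_allclose(x[0], [1, 1, 0, 1, 0], atol=1e-12)

    def test_noise_rmse_shrinks_with_n(self):
        true = np.array([0.4, 0.15, -0.05, 0.02, 0.01])
        rng = np.random.default_rng(0)

        def rmse(n_obs, reps=40):
            errs = []
            for _ in range(reps):
                doys = np.sort(rng.choice(np.arange(90, 301), n_obs, replace=False))
                vals = harmonic_design(doys) @ true + rng.normal(0, 0.05, n_obs)
                errs.append(np.mean((fit_harmonics(doys, vals) - true) ** 2))
            return np.sqrt(np.mean(errs))

        small, large = rmse(20), rmse(180)
        assert large < small / 2  # ~1/sqrt(9) expected


class TestBankAssembly:
    def test_crop_bank_shape_and_finiteness(self):
        doys, refl, valid = series_arrays(syn.MAIZE, 40, seed=2)
        fm = build_crop_bank(doys, refl, valid)
        assert list(fm.columns) == crop_feature_names()
        assert fm.shape[1] == 255
        assert np.isfinite(fm.to_numpy()).all()

    def test_unusable_series_dropped(self):
        doys, refl, valid = series_arrays(syn.MAIZE, 10, seed=2)
        valid[3] = False  # fully clouded pixel
        fm = build_crop_bank(doys, refl, valid)
        assert 3 not in fm.index
        assert len(fm) == 9

    def test_cropland_bank_shape(self, default_scene):
        idx = np.arange(0, default_scene.truth.size, 40)
        fm = build_cropland_bank(default_scene, idx)
        assert list(fm.columns) == cropland_feature_names()
        assert fm.shape[1] == 184
        assert np.isfinite(fm.to_numpy()).all()

    def test_build_bank_dispatch(self, default_scene):
        idx = np.arange(0, default_scene.truth.size, 100)
        assert build_bank("cropland", default_scene, idx).shape[1] == 184
        assert build_bank("crop", default_scene, idx).shape[1] == 255
        with pytest.raises(ValueError):
            build_bank("nope", default_scene, idx)

    def test_timeseries_features_from_smoothed_series(self):
        # a noiseless series' ts features must be smooth in time
        doys, refl, valid = series_arrays(syn.SOYBEAN, 1, seed=0)
        p = syn.noiseless(syn.default_params(syn.SOYBEAN))
        sl = syn.simulate_series(p, 1, seed=0)
        fm = build_crop_bank(sl[0].doys, sl[0].reflectance[None], sl[0].valid[None])
        ts = fm[[f"ts_ndvi_d{d:03d}" for d in GRID_STARTS]].to_numpy()[0]
        assert np.max(np.abs(np.diff(ts, 2))) < 0.05
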