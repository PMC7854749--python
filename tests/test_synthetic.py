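import numpy as np
import pytest

from conftest import series_arrays
from s2cropmap import synthetic as syn
from s2cropmap.spectral import compute_index


class TestParams:
    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            syn.PhenologyParams(syn.MAIZE, noise_sd=-0.1)

    def test_bad_flooding_window_rejected(self):
        with pytest.raises(ValueError, match="flooding_window"):
            syn.PhenologyParams(syn.RICE, flooding_window=(150, 120))
        with pytest.raises(ValueError, match="flooding_window"):
            syn.PhenologyParams(syn.RICE, flooding_window=(10, 50))

    def test_reflectance_bounds_rejected(self):
        with pytest.raises(ValueError, match="peak"):
            syn.PhenologyParams(syn.MAIZE, peak=np.full(8, 1.5))

    def test_cloud_prob_bounds(self):
        with pytest.raises(ValueError, match="cloud_prob"):
            syn.PhenologyParams(syn.MAIZE, cloud_prob=1.5)

    def test_only_rice_floods_by_default(self):
        assert syn.default_params(syn.RICE).flooding_window == (120.0, 150.0)
        for code in (syn.MAIZE, syn.SOYBEAN):
            assert syn.default_params(code).flooding_window is None
        for p in syn.default_params(syn.OTHER):
            assert p.flooding_window is None

    def test_class_code_bijection(self):
        assert syn.CLASS_LABELS == {0: "rice", 1: "maize", 2: "soybean", 3: "other"}
        assert all(syn.CLASS_CODES[v] == k for k, v in syn.CLASS_LABELS.items())


class TestSimulateSeries:
    def test_deterministic_for_seed(self):
        a = syn.simulate_series(syn.default_params(syn.MAIZE), 5, seed=42)
        b = syn.simulate_series(syn.default_params(syn.MAIZE), 5, seed=42)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.doys, sb.doys)
            np.testing.assert_array_equal(sa.reflectance, sb.reflectance)
            np.testing.assert_array_equal(sa.valid, sb.valid)

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError, match="n must"):
            syn.simulate_series(syn.default_params(syn.RICE), 0, seed=0)

    def test_reflectance_in_unit_interval(self):
        for code in range(4):
            _, refl, _ = series_arrays(code, 50, seed=9)
            assert refl.min() >= 0.0 and refl.max() <= 1.0

    def test_doys_within_year(self):
        doys, _, _ = series_arrays(syn.RICE, 1, seed=0)
        assert doys[0] >= 1 and doys[-1] <= 366
        assert np.all(np.diff(doys) > 0)

    def test_noiseless_rice_identical_and_flood_wet(self):
        p = syn.noiseless(syn.default_params(syn.RICE))
        series = syn.simulate_series(p, 5, seed=0)
        for s in series[1:]:
            np.testing.assert_array_equal(s.reflectance, series[0].reflectance)
        assert all(s.valid.all() for s in series)
        # flooding-window rice LSWI exceeds growth-stage soybean LSWI
        doys = series[0].doys
        rice_lswi = compute_index(series[0].reflectance, "lswi")
        flood = (doys >= 120) & (doys <= 150)
        soy = syn.simulate_series(syn.noiseless(syn.default_params(syn.SOYBEAN)),
                                  1, seed=0)[0]
        soy_lswi = compute_index(soy.reflectance, "lswi")
        growth = (soy.doys >= 170) & (soy.doys <= 230)
        assert rice_lswi[flood].mean() > soy_lswi[growth].mean()

    def test_cloud_prob_one_all_invalid(self):
        import dataclasses
        p = dataclasses.replace(syn.default_params(syn.MAIZE), cloud_prob=1.0)
        series = syn.simulate_series(p, 3, seed=0)
        assert all(not s.valid.any() for s in series)

    def test_cloud_prob_zero_all_valid(self):
        import dataclasses
        p = dataclasses.replace(syn.default_params(syn.MAIZE), cloud_prob=0.0)
        series = syn.simulate_series(p, 3, seed=0)
        assert all(s.valid.all() for s in series)

    def test_clouds_brighten_visible_bands(self):
        doys, refl, valid = series_arrays(syn.SOYBEAN, 200, seed=5)
        cloudy, clear = ~valid, valid
        for band in ("blue", "red"):
            v = compute_index(refl, band)
            assert v[cloudy].mean() > v[clear].mean() + 0.1


@pytest.fixture(scope="module")
def class_arrays():
    return {code: series_arrays(code, 100, seed=1) for code in range(3)}


class TestSeparabilityContract:
    """Class orderings the real features exploit, in expectation (n=100/class)."""

    def _window_mean(self, arrays, code, name, lo, hi):
        doys, refl, valid = arrays[code]
        m = (doys >= lo) & (doys <= hi)
        vals = compute_index(refl, name)[:, m]
        return np.nanmean(vals[valid[:, m]])

    @pytest.mark.parametrize("band", ["swir1", "swir2"])
    def test_rice_swir_depressed_in_flooding_window(self, class_arrays, band):
        rice = self._window_mean(class_arrays, syn.RICE, band, 120, 150)
        assert rice < self._window_mean(class_arrays, syn.MAIZE, band, 120, 150)
        assert rice < self._window_mean(class_arrays, syn.SOYBEAN, band, 120, 150)

    @pytest.mark.parametrize("index", ["lswi", "ndsvi"])
    def test_rice_wetness_elevated_in_flooding_window(self, class_arrays, index):
        rice = self._window_mean(class_arrays, syn.RICE, index, 120, 150)
        assert rice > self._window_mean(class_arrays, syn.MAIZE, index, 120, 150)
        assert rice > self._window_mean(class_arrays, syn.SOYBEAN, index, 120, 150)

    @pytest.mark.parametrize("index", ["rendvi", "rep"])
    def test_maize_red_edge_above_soybean_at_peak(self, class_arrays, index):
        maize = self._window_mean(class_arrays, syn.MAIZE, index, 200, 240)
        soy = self._window_mean(class_arrays, syn.SOYBEAN, index, 200, 240)
        assert maize > soy


class TestSimulateScene:
    def test_class_frequencies_match_mix(self):
        scene = syn.simulate_scene(100, 100, (0.3, 0.4, 0.3, 0.0), seed=11)
        freq = np.bincount(scene.truth.ravel(), minlength=4) / scene.truth.size
        np.testing.assert_allclose(freq, (0.3, 0.4, 0.3, 0.0), atol=0.05)

    def test_single_class_scene_constant(self):
        scene = syn.simulate_scene(20, 20, (0.0, 1.0, 0.0, 0.0), seed=0)
        assert np.all(scene.truth == syn.MAIZE)

    def test_forced_small_patch(self):
        scene = syn.simulate_scene(30, 30, (0.0, 1.0, 0.0, 0.0), seed=0,
                                   small_patch=(10, 10, 3, syn.SOYBEAN))
        patch = scene.truth[10:13, 10:13]
        assert np.all(patch == syn.SOYBEAN)
        area_m2 = patch.size * scene.pixel_size**2
        assert area_m2 == 900 < 1000  # strictly below 0.1 ha

    def test_empty_grid_error(self):
        with pytest.raises(ValueError, match="nonempty"):
            syn.simulate_scene(0, 10, (1, 0, 0, 0), seed=0)

    def test_bad_mix_error(self):
        with pytest.raises(ValueError, match="class_mix"):
            syn.simulate_scene(10, 10, (0.5, 0.4, 0.4, 0.0), seed=0)

    def test_deterministic(self):
        a = syn.simulate_scene(15, 15, (0.25, 0.25, 0.25, 0.25), seed=4)
        b = syn.simulate_scene(15, 15, (0.25, 0.25, 0.25, 0.25), seed=4)
        np.testing.assert_array_equal(a.truth, b.truth)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)
        np.testing.assert_array_equal(a.valid, b.valid)

    def test_scene_shapes_consistent(self, default_scene):
        npix = default_scene.truth.size
        t = len(default_scene.doys)
        assert default_scene.reflectance.shape == (npix, t, 8)
        assert default_scene.valid.shape == (npix, t)
        assert set(np.unique(default_scene.truth)) <= {0, 1, 2, 3}
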