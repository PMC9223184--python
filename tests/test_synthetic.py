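"""Synthetic scene / CAT / feature-table generator behavior."""

import numpy as np
import pytest

import moldscan as ms
from moldscan.synthetic import EMBRYO_FACTORS


class TestSceneConfig:
    def test_rejects_nonmonotone_scales(self):
        with pytest.raises(ValueError, match="decreasing"):
            ms.SceneConfig(level_reflectance_scale=(1.0, 0.9, 0.95, 0.6))

    def test_rejects_decreasing_noise(self):
        with pytest.raises(ValueError, match="nondecreasing"):
            ms.SceneConfig(texture_noise_sd=(0.05, 0.03, 0.05, 0.07))

    def test_rejects_tiny_population(self):
        with pytest.raises(ValueError):
            ms.SceneConfig(n_per_level=1)

    def test_wavelength_axes_increasing(self):
        cfg = ms.SceneConfig()
        for sensor in (ms.VIS_SWNIR, ms.LWNIR):
            lam = cfg.wavelengths(sensor)
            assert np.all(np.diff(lam) > 0)
        assert cfg.wavelengths(ms.VIS_SWNIR).size == 389
        assert cfg.wavelengths(ms.LWNIR).size == 112


class TestGenerateScene:
    def test_same_seed_bitwise_identical(self, small_scene):
        cfg, raw, white, black, truth = small_scene
        raw2, white2, black2, truth2 = ms.generate_scene(cfg, "moderate", 7)
        assert np.array_equal(raw.values, raw2.values)
        assert np.array_equal(white.values, white2.values)
        assert np.array_equal(truth.reflectance, truth2.reflectance)

    def test_acquisition_model_and_bounds(self, small_scene):
        cfg, raw, white, black, truth = small_scene
        assert np.all(white.values > black.values)
        assert truth.reflectance.min() >= 0.0
        assert truth.reflectance.max() <= 1.05
        expected = black.values + (white.values - black.values) * truth.reflectance
        np.testing.assert_allclose(raw.values, expected, rtol=0, atol=1e-12)

    def test_noise_off_variance_is_structural_only(self):
        cfg = ms.SceneConfig(spatial_size=(48, 48), vis_bands=8, lwnir_bands=8,
                             texture_noise_sd=(0, 0, 0, 0),
                             white_noise_sd=0, black_noise_sd=0)
        _, _, _, truth = ms.generate_scene(cfg, "healthy", 0)
        # with speckle off the scene is a deterministic structure: a second
        # draw from an independent stream is bitwise identical
        _, _, _, truth2 = ms.generate_scene(cfg, "healthy", 999)
        assert np.array_equal(truth.reflectance, truth2.reflectance)
        # kernel body is constant per band; the embryo dips smoothly between
        # the embryo factor and the body value
        body = truth.reflectance[truth.roi_mask.values & ~truth.embryo_mask]
        embryo = truth.reflectance[truth.embryo_mask]
        assert np.ptp(body, axis=0).max() == 0.0
        assert np.all(embryo <= body[0][None, :] + 1e-12)
        assert np.all(embryo >= 0.60 * body[0][None, :] - 1e-12)
        # within-ROI variance equals the variance of that structural profile
        roi = truth.reflectance[truth.roi_mask.values]
        assert np.all(roi.var(axis=0) > 0)

    def test_roi_mean_strictly_decreasing_across_levels(self):
        cfg = ms.SceneConfig(spatial_size=(48, 48), vis_bands=12, lwnir_bands=8,
                             texture_noise_sd=(0, 0, 0, 0),
                             white_noise_sd=0, black_noise_sd=0)
        means = []
        for level in ms.LEVELS:
            _, _, _, truth = ms.generate_scene(cfg, level, 0)
            means.append(truth.reflectance[truth.roi_mask.values].mean(axis=0))
        means = np.asarray(means)
        assert np.all(np.diff(means, axis=0) < 0)

    def test_rejects_scene_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            ms.generate_scene(ms.SceneConfig(spatial_size=(4, 4)), "healthy", 0)

    def test_rejects_unknown_level(self):
        with pytest.raises(ValueError, match="unknown"):
            ms.generate_scene(ms.SceneConfig(), "rotten", 0)


class TestGenerateCat:
    def test_healthy_all_exactly_zero(self):
        vals = ms.generate_cat(ms.CatParams(), "healthy", 60, 0)
        assert vals.shape == (60,)
        assert np.all(vals == 0.0)

    def test_degenerate_sd_gives_constant(self):
        params = ms.CatParams(sds=(0.0, 0.13, 0.09, 0.0))
        vals = ms.generate_cat(params, "severe", 25, 3)
        assert np.all(vals == 2.24)

    def test_truncation_keeps_values_nonnegative(self):
        params = ms.CatParams(means=(0.0, 0.05, 1.91, 2.24), sds=(0.0, 0.5, 0.09, 0.12))
        vals = ms.generate_cat(params, "mild", 2000, 9)
        assert np.all(vals >= 0)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            ms.generate_cat(ms.CatParams(), "fuzzy", 5, 0)

    def test_healthy_params_must_be_zero(self):
        with pytest.raises(ValueError):
            ms.CatParams(means=(0.1, 1.57, 1.91, 2.24))


class TestFeatureTables:
    def test_shapes_match_design(self, small_tables):
        cfg, tables = small_tables
        n = 4 * cfg.n_per_level
        assert tables.spectra[ms.VIS_SWNIR].matrix.shape == (n, cfg.vis_bands)
        assert tables.spectra[ms.LWNIR].matrix.shape == (n, cfg.lwnir_bands)
        for p in ("contrast", "correlation", "energy", "homogeneity"):
            assert tables.texture[ms.LWNIR][p].matrix.shape == (n, cfg.lwnir_bands)

    def test_default_design_is_240_by_389(self):
        tables = ms.generate_feature_tables(ms.SceneConfig(seed=2))
        assert tables.spectra[ms.VIS_SWNIR].matrix.shape == (240, 389)
        assert tables.texture[ms.LWNIR]["contrast"].matrix.shape == (240, 112)

    def test_label_balance(self, small_tables):
        cfg, tables = small_tables
        counts = tables.records["level"].value_counts()
        assert all(counts[lv] == cfg.n_per_level for lv in ms.LEVELS)

    def test_noise_off_class_means_are_base_times_scale(self):
        cfg = ms.SceneConfig(n_per_level=3, vis_bands=16, lwnir_bands=12,
                             spatial_size=(48, 48),
                             texture_noise_sd=(0, 0, 0, 0), seed=5)
        tables = ms.generate_feature_tables(cfg)
        for sensor in (ms.VIS_SWNIR, ms.LWNIR):
            lam = cfg.wavelengths(sensor)
            base = ms.base_spectrum(sensor, lam)
            X = tables.spectra[sensor].matrix
            for li, level in enumerate(ms.LEVELS):
                rows = X[tables.labels == level]
                expected = np.broadcast_to(
                    base * cfg.level_reflectance_scale[li], rows.shape
                )
                np.testing.assert_allclose(rows, expected, atol=1e-12)

    def test_texture_class_means_ordered_by_level(self, small_tables):
        cfg, tables = small_tables
        for sensor in (ms.VIS_SWNIR, ms.LWNIR):
            contrast = tables.texture[sensor]["contrast"].matrix
            energy = tables.texture[sensor]["energy"].matrix
            c_means = [contrast[tables.labels == lv].mean() for lv in ms.LEVELS]
            e_means = [energy[tables.labels == lv].mean() for lv in ms.LEVELS]
            assert np.all(np.diff(c_means) > 0), f"{sensor} contrast not increasing"
            assert np.all(np.diff(e_means) < 0), f"{sensor} energy not decreasing"

    def test_same_seed_identical_tables(self):
        cfg = ms.SceneConfig(n_per_level=3, vis_bands=12, lwnir_bands=8, seed=21)
        t1 = ms.generate_feature_tables(cfg)
        t2 = ms.generate_feature_tables(cfg)
        assert np.array_equal(t1.spectra[ms.VIS_SWNIR].matrix, t2.spectra[ms.VIS_SWNIR].matrix)
        assert np.array_equal(t1.texture[ms.LWNIR]["energy"].matrix,
                              t2.texture[ms.LWNIR]["energy"].matrix)
        assert t1.records.equals(t2.records)


class TestSpectralLandmarks:
    def test_vis_peak_near_820nm(self):
        lam = np.linspace(399, 1001, 389)
        base = ms.base_spectrum(ms.VIS_SWNIR, lam)
        assert abs(lam[np.argmax(base)] - 820) < 5
        # rising toward the peak, then slowly falling
        rise = base[lam < 820]
        assert np.all(np.diff(rise) > 0)
        fall = base[lam > 830]
        assert np.all(np.diff(fall) < 0)
        assert abs(fall[0] - fall[-1]) < 0.15  # the fall is slow

    def test_lwnir_peaks_and_troughs(self):
        lam = np.linspace(1005, 1701, 697)  # 1 nm grid for landmark location
        base = ms.base_spectrum(ms.LWNIR, lam)
        d = np.diff(base)
        peaks = lam[1:-1][(d[:-1] > 0) & (d[1:] <= 0)]
        troughs = lam[1:-1][(d[:-1] < 0) & (d[1:] >= 0)]
        assert min(abs(peaks - 1100)) < 15
        assert min(abs(peaks - 1300)) < 15
        assert min(abs(troughs - 1192)) < 15
        assert min(abs(troughs - 1445)) < 15


class TestRoundTrip:
    def test_image_path_reproduces_fast_path_class_structure(self):
        """Rendering scenes and extracting features must agree with the direct
        table synthesis on class-mean spectra (within the embryo-patch bias)
        and on the texture ordering."""
        from moldscan.synthetic import EMBRYO_FACTORS, _scene_geometry

        cfg = ms.SceneConfig(n_per_level=4, vis_bands=24, lwnir_bands=24,
                             spatial_size=(48, 48), pad_bands=2, seed=13)
        roi, _, profile = _scene_geometry(cfg)
        g_mean = profile[roi].mean()
        rendered = ms.render_feature_tables(cfg, ms.CatParams(), 13)
        fast = ms.generate_feature_tables(cfg, ms.CatParams(), 13)
        for sensor in (ms.VIS_SWNIR, ms.LWNIR):
            Xr, Xf = rendered.spectra[sensor].matrix, fast.spectra[sensor].matrix
            assert Xr.shape == Xf.shape
            for li, lv in enumerate(ms.LEVELS):
                mr = Xr[rendered.labels == lv].mean(axis=0)
                mf = Xf[fast.labels == lv].mean(axis=0)
                # the image path's ROI mean carries the embryo-dip factor that
                # the fast path's noise-off identity deliberately omits
                embryo_factor = 1.0 - (1.0 - EMBRYO_FACTORS[li]) * g_mean
                assert np.all(np.abs(mr - mf * embryo_factor) / mf < 0.10)
            cr = [rendered.texture[sensor]["contrast"].matrix[rendered.labels == lv].mean()
                  for lv in ms.LEVELS]
            assert np.all(np.diff(cr) > 0)
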