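"""Reflectance calibration, masking, spectrum extraction, band trimming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import moldscan as ms
from moldscan.synthetic import EMBRYO_FACTORS


def _cube(values, lam=None, sensor="toy", calibrated=False):
    values = np.asarray(values, dtype=float)
    lam = np.arange(values.shape[2], dtype=float) + 1 if lam is None else lam
    return ms.Hypercube(values, lam, sensor, calibrated)


class TestCorrectImage:
    def setup_method(self):
        rng = np.random.default_rng(0)
        shape = (6, 5, 4)
        self.white = _cube(0.9 + 0.05 * rng.random(shape))
        self.black = _cube(0.02 + 0.01 * rng.random(shape))

    def test_raw_equals_white_gives_ones(self):
        out = ms.correct_image(_cube(self.white.values), self.white, self.black)
        np.testing.assert_allclose(out.values, 1.0)
        assert out.calibrated

    def test_raw_equals_black_gives_zeros(self):
        out = ms.correct_image(_cube(self.black.values), self.white, self.black)
        np.testing.assert_allclose(out.values, 0.0)

    def test_scalar_arithmetic(self):
        raw = _cube(np.full((1, 1, 1), 0.5))
        white = _cube(np.full((1, 1, 1), 0.9))
        black = _cube(np.full((1, 1, 1), 0.1))
        assert ms.correct_image(raw, white, black).values[0, 0, 0] == pytest.approx(0.5)

    def test_affine_invariance_under_common_gain(self, rng):
        raw = _cube(0.1 + 0.7 * rng.random((6, 5, 4)))
        out1 = ms.correct_image(raw, self.white, self.black)
        gain = 0.5 + rng.random((6, 5, 1))  # per-pixel gain, common to all three
        out2 = ms.correct_image(
            _cube(raw.values * gain), _cube(self.white.values * gain),
            _cube(self.black.values * gain),
        )
        np.testing.assert_allclose(out1.values, out2.values, rtol=1e-10)

    def test_vanishing_denominator_names_location(self):
        white = _cube(self.white.values.copy())
        white.values[2, 3, 1] = self.black.values[2, 3, 1]
        with pytest.raises(ValueError, match=r"\(2, 3\), band 1"):
            ms.correct_image(_cube(self.white.values), white, self.black)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ms.correct_image(_cube(np.zeros((2, 2, 4))), self.white, self.black)


class TestBuildMask:
    def test_fixed_threshold_recovers_toy_roi(self):
        img = np.full((10, 10, 1), 0.1)
        img[3:7, 3:7, 0] = 0.8
        cube = _cube(img)
        mask = ms.build_mask(cube, mask_wavelength=1.0, method="fixed",
                             threshold=0.4, min_area=0)
        expected = np.zeros((10, 10), dtype=bool)
        expected[3:7, 3:7] = True
        assert np.array_equal(mask.values, expected)

    def test_otsu_on_synthetic_scene_matches_truth(self, small_scene):
        cfg, raw, white, black, truth = small_scene
        cube = ms.correct_image(raw, white, black)
        mask = ms.build_mask(cube)
        tm, fm = truth.roi_mask.values, mask.values
        recall = (tm & fm).sum() / tm.sum()
        false_fg = (fm & ~tm).sum() / fm.sum()
        assert recall >= 0.95
        assert false_fg <= 0.05

    def test_all_background_raises(self):
        cube = _cube(np.full((10, 10, 1), 0.1))
        with pytest.raises(ValueError, match="no ROI"):
            ms.build_mask(cube, mask_wavelength=1.0, method="fixed", threshold=0.4)

    def test_wavelength_outside_range_rejected(self, small_scene):
        _, raw, *_ = small_scene
        with pytest.raises(ValueError, match="outside"):
            ms.build_mask(raw, mask_wavelength=2000.0)


class TestExtractMeanSpectrum:
    def test_constant_cube(self):
        cube = _cube(np.full((4, 4, 3), 0.42))
        mask = ms.Mask(np.ones((4, 4), dtype=bool))
        np.testing.assert_allclose(ms.extract_mean_spectrum(cube, mask), 0.42)

    def test_two_pixel_average(self):
        img = np.zeros((1, 3, 1))
        img[0, 0, 0], img[0, 1, 0] = 0.2, 0.4
        mask = ms.Mask(np.array([[True, True, False]]))
        assert ms.extract_mean_spectrum(_cube(img), mask)[0] == pytest.approx(0.3)

    def test_empty_mask_rejected(self):
        cube = _cube(np.zeros((2, 2, 1)))
        with pytest.raises(ValueError, match="empty mask"):
            ms.extract_mean_spectrum(cube, ms.Mask(np.zeros((2, 2), dtype=bool)))

    def test_noise_off_scene_mean_is_exact(self):
        """With all noise off the ROI mean follows from the construction:
        base x scale over the kernel body, dipped by the embryo depth profile
        over the embryo patch."""
        from moldscan.synthetic import _scene_geometry

        cfg = ms.SceneConfig(spatial_size=(48, 48), vis_bands=10, lwnir_bands=8,
                             texture_noise_sd=(0, 0, 0, 0),
                             white_noise_sd=0, black_noise_sd=0)
        roi, _, profile = _scene_geometry(cfg)
        for li, level in enumerate(ms.LEVELS):
            raw, white, black, truth = ms.generate_scene(cfg, level, 0)
            cube = ms.correct_image(raw, white, black)
            base = ms.base_spectrum(ms.VIS_SWNIR, cube.wavelengths)
            expected_body = base * cfg.level_reflectance_scale[li]
            body = ms.Mask(truth.roi_mask.values & ~truth.embryo_mask)
            np.testing.assert_allclose(
                ms.extract_mean_spectrum(cube, body), expected_body, rtol=1e-9
            )
            factor = 1.0 - (1.0 - EMBRYO_FACTORS[li]) * profile[roi].mean()
            np.testing.assert_allclose(
                ms.extract_mean_spectrum(cube, truth.roi_mask),
                expected_body * factor, rtol=1e-9,
            )

    def test_mean_bounded_by_roi_extremes(self, small_scene):
        cfg, raw, white, black, truth = small_scene
        cube = ms.correct_image(raw, white, black)
        spec = ms.extract_mean_spectrum(cube, truth.roi_mask)
        roi = cube.values[truth.roi_mask.values]
        assert np.all(spec >= roi.min(axis=0)) and np.all(spec <= roi.max(axis=0))


class TestTrimBands:
    def test_toy_window(self):
        lam = np.arange(1.0, 11.0)
        X = np.arange(20, dtype=float).reshape(2, 10)
        out, lam_t = ms.trim_bands(X, lam, 3, 7)
        assert out.shape == (2, 5)
        np.testing.assert_array_equal(lam_t, [3, 4, 5, 6, 7])

    def test_full_range_is_identity(self):
        lam = np.arange(1.0, 11.0)
        X = np.ones((2, 10))
        out, lam_t = ms.trim_bands(X, lam, 0, 100)
        assert np.array_equal(out, X) and np.array_equal(lam_t, lam)

    def test_generator_padded_axis_trims_to_configured_bands(self):
        cfg = ms.SceneConfig(vis_bands=40, pad_bands=6)
        lam = cfg.wavelengths(ms.VIS_SWNIR, padded=True)
        assert lam.size == 52
        X = np.zeros((3, 52))
        out, lam_t = ms.trim_bands(X, lam, *cfg.vis_range)
        assert out.shape == (3, 40)
        np.testing.assert_allclose(lam_t, cfg.wavelengths(ms.VIS_SWNIR))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(1, 8), st.integers(1, 8), st.integers(0, 3), st.integers(0, 3))
    def test_nested_trims_compose(self, lo, hi, dlo, dhi):
        lam = np.arange(0.0, 12.0)
        X = np.arange(12.0)[None, :]
        lo, hi = sorted((lo, hi + 8))
        inner = (lo + dlo, max(lo + dlo + 1, hi - dhi))
        once, lam1 = ms.trim_bands(X, lam, *inner)
        outer, lam2 = ms.trim_bands(X, lam, lo, hi)
        twice, lam3 = ms.trim_bands(outer, lam2, *inner)
        assert np.array_equal(once, twice) and np.array_equal(lam1, lam3)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="no bands"):
            ms.trim_bands(np.ones((1, 5)), np.arange(5.0), 90, 99)


class TestHypercubeInvariants:
    def test_wavelength_band_mismatch_rejected(self):
        with pytest.raises(ValueError, match="band count"):
            ms.Hypercube(np.zeros((2, 2, 3)), np.arange(2.0), "toy")

    def test_nonmonotone_axis_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ms.Hypercube(np.zeros((2, 2, 3)), np.array([1.0, 3.0, 2.0]), "toy")

    def test_sensor_range_enforced(self):
        with pytest.raises(ValueError, match="range"):
            ms.Hypercube(np.zeros((2, 2, 2)), np.array([100.0, 500.0]), ms.VIS_SWNIR)
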