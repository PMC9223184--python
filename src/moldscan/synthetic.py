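"""Synthetic two-sensor hyperspectral scenes, CAT measurements and feature tables.

The study conditions emulated here: four mold severity levels (healthy,
mild, moderate, severe; 60 samples each), where more severe mold depresses
overall reflectance and increases spatial texture heterogeneity
concentrated in the kernel's embryo patch.  Two sensors are modeled:

* Vis-SWNIR — 389 retained bands over 399-1001 nm; base reflectance rises
  from 399 nm to a peak near 820 nm then falls slowly.
* LWNIR — 112 retained bands over 1005-1701 nm; reflectance peaks near
  1100 and 1300 nm with absorption troughs near 1192 and 1445 nm.

Catalase (CAT) activity per level follows the measured grading statistics:
healthy exactly 0, and mild/moderate/severe Gaussian with means
1.57 / 1.91 / 2.24 mL/(h·g) and SDs 0.13 / 0.09 / 0.12 (truncated at zero
by redraw).

Two fidelity levels are provided: full image rendering (``generate_scene``)
for modest scene counts, and direct feature-table synthesis
(``generate_feature_tables``) whose texture class means are calibrated
against rendered scenes so the fast path statistically matches the
image-processing path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import LEVELS, LWNIR, VIS_SWNIR, Hypercube, Mask
from .preprocessing import SpectraMatrix
from .texture import TEXTURE_PARAMS, GlcmSpec, TextureBlock, band_texture_row

CULTURE_DAYS = {"healthy": 0, "mild": 2, "moderate": 4, "severe": 6}

#: Embryo reflectance multiplier per level: the embryo patch deviates
#: further from the kernel body as mold advances.  The step is kept large
#: relative to the speckle spread so per-band min-max quantization stays
#: structure-dominated and texture statistics vary monotonically with the
#: level's speckle SD.
EMBRYO_FACTORS = (0.60, 0.55, 0.50, 0.45)

#: Fraction of in-ROI speckle SD applied outside the embryo patch.
BODY_SPECKLE_FRACTION = 1.0 / 3.0

BACKGROUND_REFLECTANCE = 0.05


@dataclass
class SceneConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_per_level: int = 60
    levels: tuple[str, ...] = LEVELS
    spatial_size: tuple[int, int] = (64, 64)
    vis_bands: int = 389
    vis_range: tuple[float, float] = (399.0, 1001.0)
    lwnir_bands: int = 112
    lwnir_range: tuple[float, float] = (1005.0, 1701.0)
    level_reflectance_scale: tuple[float, ...] = (1.00, 0.85, 0.72, 0.60)
    texture_noise_sd: tuple[float, ...] = (0.01, 0.03, 0.05, 0.07)
    embryo_patch_fraction: float = 0.15
    pad_bands: int = 0
    white_noise_sd: float = 0.003
    black_noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_level < 2:
            raise ValueError("need at least 2 samples per level")
        if len(self.level_reflectance_scale) != len(self.levels):
            raise ValueError("one reflectance scale per level required")
        if len(self.texture_noise_sd) != len(self.levels):
            raise ValueError("one texture noise SD per level required")
        scales = np.asarray(self.level_reflectance_scale)
        if not np.all(np.diff(scales) < 0):
            raise ValueError("reflectance scale factors must be strictly decreasing")
        sds = np.asarray(self.texture_noise_sd)
        if np.any(sds < 0) or not np.all(np.diff(sds) >= 0):
            raise ValueError("texture noise SDs must be nonnegative and nondecreasing")
        if not (0 < self.embryo_patch_fraction < 1):
            raise ValueError("embryo patch fraction must be in (0, 1)")

    def wavelengths(self, sensor: str, padded: bool = False) -> np.ndarray:
        """Retained wavelength grid for a sensor; ``padded`` adds noise bands
        beyond both ends (emulating the trimmed-away ends of the raw axis)."""
        if sensor == VIS_SWNIR:
            lo, hi = self.vis_range
            n = self.vis_bands
        elif sensor == LWNIR:
            lo, hi = self.lwnir_range
            n = self.lwnir_bands
        else:
            raise ValueError(f"unknown sensor {sensor!r}")
        axis = np.linspace(lo, hi, n)
        if padded and self.pad_bands > 0:
            step = (hi - lo) / (n - 1)
            before = lo - step * np.arange(self.pad_bands, 0, -1)
            after = hi + step * np.arange(1, self.pad_bands + 1)
            axis = np.concatenate([before, axis, after])
        return axis

    def level_index(self, level: str) -> int:
        if level not in self.levels:
            raise ValueError(f"unknown mold level {level!r}")
        return self.levels.index(level)


@dataclass
class CatParams:
    """Per-level mean/SD of catalase activity in mL/(h·g)."""

    means: tuple[float, ...] = (0.0, 1.57, 1.91, 2.24)
    sds: tuple[float, ...] = (0.0, 0.13, 0.09, 0.12)
    levels: tuple[str, ...] = LEVELS

    def __post_init__(self) -> None:
        if len(self.means) != len(self.levels) or len(self.sds) != len(self.levels):
            raise ValueError("one mean and SD per level required")
        if self.means[0] != 0.0 or self.sds[0] != 0.0:
            raise ValueError("healthy level must have mean and SD exactly 0")
        nonhealthy = np.asarray(self.means[1:])
        if not np.all(np.diff(nonhealthy) > 0):
            raise ValueError("non-healthy CAT means must be strictly increasing")
        if any(s < 0 for s in self.sds):
            raise ValueError("CAT SDs must be nonnegative")


@dataclass
class SceneTruth:
    """Ground truth for a rendered scene: noise-free reflectance and masks."""

    reflectance: np.ndarray
    roi_mask: Mask
    embryo_mask: np.ndarray
    level: str


def base_spectrum(sensor: str, wavelengths: np.ndarray) -> np.ndarray:
    """Healthy-kernel base reflectance curve for one sensor.

    Smooth analytic mixtures placing the documented landmarks: Vis-SWNIR
    peaks at 820 nm (asymmetric Gaussian: fast rise, slow fall); LWNIR has
    Gaussian peaks at 1100/1300 nm and troughs at 1192/1445 nm.
    """
    lam = np.asarray(wavelengths, dtype=np.float64)
    if sensor == VIS_SWNIR:
        width = np.where(lam <= 820.0, 230.0, 900.0)
        g = np.exp(-(((lam - 820.0) / width) ** 2))
        return 0.12 + 0.68 * g
    if sensor == LWNIR:
        return (
            0.45
            + 0.18 * np.exp(-(((lam - 1100.0) / 55.0) ** 2))
            + 0.16 * np.exp(-(((lam - 1300.0) / 70.0) ** 2))
            - 0.12 * np.exp(-(((lam - 1192.0) / 40.0) ** 2))
            - 0.18 * np.exp(-(((lam - 1445.0) / 80.0) ** 2))
        )
    raise ValueError(f"unknown sensor {sensor!r}")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _scene_geometry(config: SceneConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Elliptical kernel ROI, embryo mask and embryo depth profile.

    The embryo is a smaller ellipse offset toward the top of the kernel,
    sized to cover the configured fraction of the ROI area.  Its profile
    ``g`` fades smoothly from 1 at the center to 0 at the rim — a gradient
    rather than a step, like a real embryo's gradual boundary; a sharp step
    would concentrate the quantization range on two extreme gray levels and
    make texture statistics erratic.
    """
    h, w = config.spatial_size
    r, c = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a, b = 0.36 * h, 0.30 * w
    roi = ((r - cy) / a) ** 2 + ((c - cx) / b) ** 2 <= 1.0
    s = np.sqrt(config.embryo_patch_fraction)
    ey = cy - 0.35 * a
    r2 = ((r - ey) / (s * a)) ** 2 + ((c - cx) / (s * b)) ** 2
    embryo = (r2 <= 1.0) & roi
    profile = np.where(embryo, np.maximum(1.0 - r2, 0.0), 0.0)
    if roi.sum() < 16 or embryo.sum() < 4:
        raise ValueError(
            f"spatial size {config.spatial_size} too small to contain ROI and embryo patch"
        )
    return roi, embryo, profile


def generate_scene(
    config: SceneConfig,
    level: str,
    rng,
    sensor: str = VIS_SWNIR,
) -> tuple[Hypercube, Hypercube, Hypercube, SceneTruth]:
    """Render one sample's raw/white/black cubes plus ground truth.

    The true reflectance scene is built first (elliptical kernel on a dark
    background, base curve scaled by the level factor, embryo patch deviating
    further, multiplicative speckle with the level's SD inside the embryo and
    a third of it elsewhere in the ROI), then folded through the acquisition
    model ``raw = black + (white - black) * R``.
    """
    idx = config.level_index(level)
    rng = _as_rng(rng)
    lam = config.wavelengths(sensor, padded=True)
    roi, embryo, profile = _scene_geometry(config)
    h, w = roi.shape
    n_bands = lam.size

    sd = config.texture_noise_sd[idx]
    # whole-kernel multiplicative scatter: one amplitude draw per scene, the
    # same between-sample variation the fast table path uses
    amp = 1.0 + SPECTRA_SAMPLE_SD_FACTOR * sd * rng.standard_normal()
    base = base_spectrum(sensor, lam) * config.level_reflectance_scale[idx] * amp
    # reflectance multiplier: 1 over the kernel body, dipping smoothly to the
    # level's embryo factor at the embryo center
    mult = np.where(roi, 1.0 - (1.0 - EMBRYO_FACTORS[idx]) * profile, 0.0)
    refl = np.full((h, w, n_bands), BACKGROUND_REFLECTANCE)
    refl[roi] = base[None, :] * mult[roi][:, None]

    if sd > 0:
        speckle = rng.standard_normal((h, w, n_bands))
        gain = np.where(
            embryo[:, :, None], sd,
            np.where(roi[:, :, None], sd * BODY_SPECKLE_FRACTION, 0.0),
        )
        refl = refl * (1.0 + gain * speckle)
    np.clip(refl, 0.0, 1.05, out=refl)

    white_vals = 0.99 + config.white_noise_sd * rng.standard_normal((h, w, n_bands))
    black_vals = 0.02 + config.black_noise_sd * rng.standard_normal((h, w, n_bands))
    raw_vals = black_vals + (white_vals - black_vals) * refl

    raw = Hypercube(raw_vals, lam, sensor, calibrated=False)
    white = Hypercube(white_vals, lam.copy(), sensor, calibrated=False)
    black = Hypercube(black_vals, lam.copy(), sensor, calibrated=False)
    truth = SceneTruth(refl, Mask(roi), embryo, level)
    return raw, white, black, truth


def generate_cat(params: CatParams, level: str, n: int, rng) -> np.ndarray:
    """Draw ``n`` CAT activity values for a level.

    Healthy samples are exactly 0 (sterilized kernels have no mold
    metabolism); other levels draw from a Gaussian truncated at 0 by redraw,
    which keeps the sample mean at the configured target.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if level not in params.levels:
        raise ValueError(f"unknown mold level {level!r}")
    idx = params.levels.index(level)
    mean, sd = params.means[idx], params.sds[idx]
    if idx == 0:
        return np.zeros(n)
    rng = _as_rng(rng)
    out = mean + sd * rng.standard_normal(n)
    while True:
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = mean + sd * rng.standard_normal(int(neg.sum()))


# --- fast path: direct feature-table synthesis -------------------------------

#: Between-sample multiplicative spectral variation, as a multiple of the
#: level's speckle SD (a whole-kernel scatter effect).
SPECTRA_SAMPLE_SD_FACTOR = 1.0
#: Per-band additive spectral noise, as a multiple of the level's speckle SD.
SPECTRA_BAND_SD_FACTOR = 0.1
#: Between-sample relative variation of texture parameter rows.
TEXTURE_SAMPLE_SD = 0.15
#: Per-band relative noise of texture parameter rows.
TEXTURE_BAND_SD = 0.05

#: Number of bands actually rendered when calibrating fast-path texture
#: class means; values at the remaining bands are interpolated.
_TEXTURE_CALIB_BANDS = 24
#: Scenes rendered and averaged per (level, sensor) during calibration.
_TEXTURE_CALIB_SCENES = 2


@dataclass
class FeatureTables:
    """Fast-path dataset: per-sensor spectra, texture blocks and sample records."""

    spectra: dict[str, SpectraMatrix]
    texture: dict[str, dict[str, TextureBlock]]
    records: pd.DataFrame
    labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = self.records["level"].to_numpy()


def _texture_class_means(
    config: SceneConfig, sensor: str, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-level texture parameter curves, calibrated by rendering one scene
    per level on a coarse band grid and interpolating to the full axis."""
    lam = config.wavelengths(sensor)
    sub = np.unique(np.linspace(0, lam.size - 1, min(_TEXTURE_CALIB_BANDS, lam.size)).astype(int))
    spec = GlcmSpec()
    out = {p: np.empty((len(config.levels), lam.size)) for p in TEXTURE_PARAMS}
    pad = config.pad_bands
    kernel = np.ones(5) / 5.0  # light smoothing over calibration bands
    for li, level in enumerate(config.levels):
        acc = {p: np.zeros(sub.size) for p in TEXTURE_PARAMS}
        for _ in range(_TEXTURE_CALIB_SCENES):
            raw, white, black, truth = generate_scene(config, level, rng, sensor)
            refl = (raw.values - black.values) / (white.values - black.values)
            refl = refl[:, :, pad : pad + lam.size]  # drop padded noise bands
            rows = band_texture_row(refl[:, :, sub], truth.roi_mask.values, spec)
            for p in TEXTURE_PARAMS:
                acc[p] += rows[p]
        for p in TEXTURE_PARAMS:
            curve = acc[p] / _TEXTURE_CALIB_SCENES
            if curve.size >= kernel.size:
                pad_c = np.concatenate(
                    [np.full(2, curve[0]), curve, np.full(2, curve[-1])]
                )
                curve = np.convolve(pad_c, kernel, mode="valid")
            out[p][li] = np.interp(lam, lam[sub], curve)
    return out


def generate_feature_tables(
    config: SceneConfig,
    cat_params: CatParams | None = None,
    rng=None,
) -> FeatureTables:
    """Synthesize ready-made feature tables for the full balanced experiment.

    Spectra rows are the level's base curve times a per-sample multiplicative
    factor (SD proportional to the level's speckle SD) plus per-band noise;
    class means with noise off are exactly base curve x scale factor.
    Texture rows jitter around class-mean curves calibrated from rendered
    scenes, so class ordering (contrast increasing, energy decreasing with
    mold) matches the image-processing path.
    """
    cat_params = cat_params or CatParams()
    rng = _as_rng(config.seed if rng is None else rng)
    n_levels = len(config.levels)
    n_total = config.n_per_level * n_levels

    records = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n_total)],
            "level": np.repeat(list(config.levels), config.n_per_level),
            "culture_day": np.repeat(
                [CULTURE_DAYS.get(lv, 0) for lv in config.levels], config.n_per_level
            ),
        }
    )
    cat_vals = np.concatenate(
        [generate_cat(cat_params, lv, config.n_per_level, rng) for lv in config.levels]
    )
    records["cat_activity"] = cat_vals

    spectra: dict[str, SpectraMatrix] = {}
    texture: dict[str, dict[str, TextureBlock]] = {}
    for sensor in (VIS_SWNIR, LWNIR):
        lam = config.wavelengths(sensor)
        base = base_spectrum(sensor, lam)
        X = np.empty((n_total, lam.size))
        row = 0
        for li, level in enumerate(config.levels):
            scale = config.level_reflectance_scale[li]
            sd = config.texture_noise_sd[li]
            amp = 1.0 + SPECTRA_SAMPLE_SD_FACTOR * sd * rng.standard_normal(config.n_per_level)
            noise = SPECTRA_BAND_SD_FACTOR * sd * rng.standard_normal((config.n_per_level, lam.size))
            X[row : row + config.n_per_level] = base[None, :] * scale * amp[:, None] + noise
            row += config.n_per_level
        spectra[sensor] = SpectraMatrix(X, lam, sensor)

        class_means = _texture_class_means(config, sensor, rng)
        texture[sensor] = {}
        for p in TEXTURE_PARAMS:
            T = np.empty((n_total, lam.size))
            row = 0
            for li in range(n_levels):
                amp = 1.0 + TEXTURE_SAMPLE_SD * rng.standard_normal(config.n_per_level)
                noise = 1.0 + TEXTURE_BAND_SD * rng.standard_normal((config.n_per_level, lam.size))
                T[row : row + config.n_per_level] = class_means[p][li][None, :] * amp[:, None] * noise
                row += config.n_per_level
            if p in ("energy", "homogeneity"):
                np.clip(T, 1e-6, 1.0, out=T)
            elif p == "contrast":
                np.clip(T, 0.0, None, out=T)
            texture[sensor][p] = TextureBlock(p, T, lam, sensor)

    return FeatureTables(spectra=spectra, texture=texture, records=records)
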