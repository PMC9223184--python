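"""Reflectance calibration, ROI segmentation and mean-spectrum extraction.

Line-scan hyperspectral systems record raw intensity counts that mix the
sample signal with the lamp spectrum and the camera dark current.  The
standard correction uses a white reference (near-perfect diffuse reflector)
and a black reference (shutter closed):

    R = (I_raw - I_black) / (I_white - I_black)

After correction, kernel pixels are separated from the low-reflectance
background by thresholding a single gray band chosen where the
kernel/background contrast is largest (849 nm for the Vis-SWNIR sensor,
1098 nm for the LWNIR sensor), and the mean spectrum over the region of
interest (ROI) is the per-sample spectral observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

logger = logging.getLogger(__name__)

#: Canonical mold severity order used for every label-dependent structure.
LEVELS = ("healthy", "mild", "moderate", "severe")

VIS_SWNIR = "VIS_SWNIR"
LWNIR = "LWNIR"

#: Full sensor wavelength coverage in nm (instrument spectrograph ranges).
SENSOR_RANGES = {VIS_SWNIR: (327.0, 1098.0), LWNIR: (930.0, 2548.0)}

#: Default gray band used for mask construction, per sensor (nm).
MASK_WAVELENGTHS = {VIS_SWNIR: 849.0, LWNIR: 1098.0}

#: Noise-band trimming windows retained for analysis, per sensor (nm).
TRIM_RANGES = {VIS_SWNIR: (399.0, 1001.0), LWNIR: (1005.0, 1701.0)}

_DENOM_EPS = 1e-6


@dataclass
class Hypercube:
    """A single sample's image stack: ``values[h, w, band]`` plus wavelength axis."""

    values: np.ndarray
    wavelengths: np.ndarray
    sensor: str
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("hypercube values must be height x width x bands")
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count {self.values.shape[2]} does not match "
                f"wavelength axis length {self.wavelengths.size}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if self.sensor in SENSOR_RANGES:
            lo, hi = SENSOR_RANGES[self.sensor]
            if self.wavelengths[0] < lo - 1e-9 or self.wavelengths[-1] > hi + 1e-9:
                raise ValueError(
                    f"wavelengths outside {self.sensor} range [{lo}, {hi}] nm"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def band_nearest(self, wavelength: float) -> int:
        """Index of the band closest to ``wavelength`` (nm)."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength)))


@dataclass
class Mask:
    """Binary foreground image aligned with a cube's spatial grid."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be a 2-D binary image")

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


def correct_image(raw: Hypercube, white: Hypercube, black: Hypercube) -> Hypercube:
    """Reflectance calibration ``(raw - black) / (white - black)``.

    All three cubes must share spatial shape and wavelength axis.  Raises if
    the white/black difference vanishes anywhere (the correction would blow
    up); values outside the physically plausible band [-0.1, 1.5] are left
    untouched but logged.
    """
    for other, name in ((white, "white"), (black, "black")):
        if other.shape != raw.shape:
            raise ValueError(f"{name} reference shape {other.shape} != raw {raw.shape}")
        if not np.array_equal(other.wavelengths, raw.wavelengths):
            raise ValueError(f"{name} reference wavelength axis differs from raw")
    denom = white.values - black.values
    bad = np.abs(denom) < _DENOM_EPS
    if bad.any():
        px = np.argwhere(bad)[0]
        raise ValueError(
            "white - black below tolerance at pixel "
            f"({px[0]}, {px[1]}), band {px[2]}"
        )
    out = (raw.values - black.values) / denom
    n_out = int(np.count_nonzero((out < -0.1) | (out > 1.5)))
    if n_out:
        logger.warning("correct_image: %d values outside [-0.1, 1.5] (kept)", n_out)
    return Hypercube(out, raw.wavelengths.copy(), raw.sensor, calibrated=True)


def build_mask(
    cube: Hypercube,
    mask_wavelength: float | None = None,
    method: str = "otsu",
    threshold: float | None = None,
    fill_holes: bool = True,
    min_area: int = 20,
) -> Mask:
    """Segment the kernel ROI by thresholding one gray band.

    Parameters
    ----------
    mask_wavelength
        Band (nm) used for segmentation; defaults to the sensor's
        highest-contrast band (849 nm Vis-SWNIR, 1098 nm LWNIR).
    method
        ``"otsu"`` (default, parameter-free) or ``"fixed"`` with ``threshold``.
    fill_holes, min_area
        Morphological cleanup: fill enclosed holes and drop connected
        components smaller than ``min_area`` pixels.  Set ``fill_holes=False``
        / ``min_area=0`` to disable.
    """
    if mask_wavelength is None:
        mask_wavelength = MASK_WAVELENGTHS.get(cube.sensor, float(cube.wavelengths[0]))
    if not (cube.wavelengths[0] <= mask_wavelength <= cube.wavelengths[-1]):
        raise ValueError(
            f"mask wavelength {mask_wavelength} nm outside cube range "
            f"[{cube.wavelengths[0]}, {cube.wavelengths[-1]}]"
        )
    gray = cube.values[:, :, cube.band_nearest(mask_wavelength)]
    if method == "otsu":
        thr = float(threshold_otsu(gray))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold masking requires a threshold value")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown mask method {method!r}")
    fg = gray > thr
    if fill_holes:
        fg = ndimage.binary_fill_holes(fg)
    if min_area > 0:
        fg = remove_small_objects(fg, max_size=min_area - 1)
    if not fg.any():
        raise ValueError("no ROI found: mask empty after thresholding and cleanup")
    return Mask(fg)


def extract_mean_spectrum(cube: Hypercube, mask: Mask) -> np.ndarray:
    """Arithmetic mean reflectance over foreground pixels, per band."""
    if mask.values.shape != cube.shape[:2]:
        raise ValueError("mask spatial shape does not match cube")
    if mask.n_foreground == 0:
        raise ValueError("empty mask: no foreground pixels to average")
    return cube.values[mask.values].mean(axis=0)


def trim_bands(
    matrix: np.ndarray, wavelengths: np.ndarray, low: float, high: float
) -> tuple[np.ndarray, np.ndarray]:
    """Retain columns with ``low <= wavelength <= high`` (noise-band removal).

    Works on any samples x bands matrix (mean spectra or texture blocks) or a
    single spectrum; column order is preserved.
    """
    if low >= high:
        raise ValueError(f"invalid trim range [{low}, {high}]")
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    keep = (wavelengths >= low) & (wavelengths <= high)
    if not keep.any():
        raise ValueError(f"no bands within [{low}, {high}] nm")
    matrix = np.asarray(matrix)
    return matrix[..., keep], wavelengths[keep]
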