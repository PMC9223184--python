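"""Per-band GLCM texture parameters over a masked ROI.

For every spectral band the ROI gray image is quantized to N gray levels,
a gray-level co-occurrence matrix (GLCM) is accumulated for pixel pairs at
distance d along each of the four standard directions (0°, 45°, 90°, 135°),
and four texture statistics are computed per direction and averaged:

    contrast    = sum (i-j)^2 P(i,j)
    correlation = (sum ij P(i,j) - mu_i mu_j) / (sigma_i sigma_j)
    energy      = sum P(i,j)^2
    homogeneity = sum P(i,j) / (1 + (i-j)^2)

with mu/sigma the marginal means and standard deviations of the GLCM.
Pairs with either pixel outside the ROI are excluded (the GLCM is
conditional on the ROI, not zero-padded), and the matrix is the ordered
(non-symmetric) pair count normalized to a probability table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imaging import Hypercube, Mask

logger = logging.getLogger(__name__)

TEXTURE_PARAMS = ("contrast", "correlation", "energy", "homogeneity")

#: Row/column pixel offsets for the four standard GLCM directions.  Rows
#: increase downward, so 45° points up-right, 90° straight up, 135° up-left.
ANGLE_OFFSETS = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass
class GlcmSpec:
    """GLCM construction parameters: gray levels, pixel distance, directions."""

    gray_levels: int = 8
    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self) -> None:
        if self.gray_levels < 2:
            raise ValueError("need at least 2 gray levels")
        if self.distance < 1:
            raise ValueError("pixel distance must be >= 1")
        for a in self.angles:
            if a not in ANGLE_OFFSETS:
                raise ValueError(f"unsupported GLCM angle {a}")


@dataclass
class TextureBlock:
    """samples x bands matrix of one texture parameter, with wavelength axis."""

    parameter: str
    matrix: np.ndarray
    wavelengths: np.ndarray
    sensor: str = ""

    def __post_init__(self) -> None:
        if self.parameter not in TEXTURE_PARAMS:
            raise ValueError(f"unknown texture parameter {self.parameter!r}")
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.matrix.shape[1] != self.wavelengths.size:
            raise ValueError("texture matrix width must match wavelength axis")


def quantize(gray: np.ndarray, mask: np.ndarray, n_levels: int = 8) -> tuple[np.ndarray, bool]:
    """Bin ROI pixel values into ``n_levels`` equal-width levels 1..N.

    Bin edges span the ROI min..max of this band; background pixels are
    marked 0 (invalid).  A constant ROI maps every pixel to level 1 and the
    returned flag is True.
    """
    gray = np.asarray(gray, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to quantize")
    vals = gray[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(gray.shape, dtype=np.int64)
    if hi - lo <= 0:
        levels[mask] = 1
        return levels, True
    binned = np.floor((gray - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    np.clip(binned, 1, n_levels, out=binned)
    levels[mask] = binned[mask]
    return levels, False


def glcm(levels: np.ndarray, spec: GlcmSpec, angle: int) -> np.ndarray:
    """Ordered-pair co-occurrence probability matrix at one direction.

    ``levels`` holds gray levels 1..N with 0 marking invalid (background)
    pixels.  Counts ordered pairs (pixel, neighbor at the direction's offset
    scaled by the distance) where both pixels are valid, then normalizes to
    sum 1.  Raises if no valid pair exists.
    """
    levels = np.asarray(levels, dtype=np.int64)
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * spec.distance, dc * spec.distance
    h, w = levels.shape
    n = spec.gray_levels

    # overlapping windows: source pixel at (r, c), neighbor at (r+dr, c+dc)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"image too small for GLCM offset at angle {angle}")
    src = levels[r0:r1, c0:c1]
    dst = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (src > 0) & (dst > 0)
    if not valid.any():
        raise ValueError(f"no valid pixel pairs inside ROI at angle {angle}")
    pairs = (src[valid] - 1) * n + (dst[valid] - 1)
    counts = np.bincount(pairs, minlength=n * n).reshape(n, n).astype(np.float64)
    return counts / counts.sum()


def texture_params(P: np.ndarray) -> dict[str, float]:
    """Contrast, correlation, energy, homogeneity of one GLCM."""
    P = np.asarray(P, dtype=np.float64)
    n = P.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    diff2 = (i[:, None] - i[None, :]) ** 2
    contrast = float((diff2 * P).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + diff2)).sum())
    pi, pj = P.sum(axis=1), P.sum(axis=0)
    mu_i, mu_j = float(i @ pi), float(i @ pj)
    var_i = float(((i - mu_i) ** 2) @ pi)
    var_j = float(((i - mu_j) ** 2) @ pj)
    sd = np.sqrt(var_i * var_j)
    if sd < 1e-12:
        logger.warning("texture_params: zero marginal SD, correlation set to 0")
        correlation = 0.0
    else:
        correlation = float(((i[:, None] * i[None, :]) * P).sum() - mu_i * mu_j) / sd
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def band_texture_row(
    values: np.ndarray, mask: np.ndarray, spec: GlcmSpec | None = None
) -> dict[str, np.ndarray]:
    """Texture parameters per band for one cube's ROI (one sample row).

    Per band: quantize the ROI, build a GLCM at each configured direction,
    compute the four parameters per direction and average over directions.
    A band where some direction has no valid pair yields NaN there (logged).
    """
    spec = spec or GlcmSpec()
    n_bands = values.shape[2]
    out = {p: np.full(n_bands, np.nan) for p in TEXTURE_PARAMS}
    for b in range(n_bands):
        levels, _ = quantize(values[:, :, b], mask, spec.gray_levels)
        try:
            per_angle = [texture_params(glcm(levels, spec, a)) for a in spec.angles]
        except ValueError as exc:
            logger.warning("band %d: %s (row value set to NaN)", b, exc)
            continue
        for p in TEXTURE_PARAMS:
            out[p][b] = float(np.mean([pa[p] for pa in per_angle]))
    return out


def band_texture_matrix(
    cube: Hypercube, mask: Mask, spec: GlcmSpec | None = None
) -> dict[str, TextureBlock]:
    """Four one-row TextureBlocks (contrast/correlation/energy/homogeneity)."""
    if not cube.calibrated:
        raise ValueError("texture extraction requires a calibrated cube")
    if mask.values.shape != cube.shape[:2]:
        raise ValueError("mask spatial shape does not match cube")
    rows = band_texture_row(cube.values, mask.values, spec)
    return {
        p: TextureBlock(p, rows[p][None, :], cube.wavelengths, cube.sensor)
        for p in TEXTURE_PARAMS
    }
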