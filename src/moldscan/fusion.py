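"""Pixel-level and feature-level fusion of spectra and texture blocks.

Pixel-level fusion concatenates full data blocks column-wise; feature-level
fusion concatenates each block restricted to the columns its variable
selector retained.  Every fused column keeps provenance (sensor, block
type, original column index, wavelength), and a per-column min-max scaling
fitted on calibration rows maps features into [0, 1] before margin-based
classifiers (prediction rows may exceed the range marginally; no clamping).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .preprocessing import SpectraMatrix
from .selection import FeatureSelection
from .texture import TextureBlock

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnProvenance:
    sensor: str
    block: str  # "spectra" or a texture parameter name
    band_index: int
    wavelength: float


@dataclass
class FusedMatrix:
    matrix: np.ndarray
    provenance: tuple[ColumnProvenance, ...]
    fusion_level: str  # "pixel" or "feature"
    scale_min: np.ndarray | None = None
    scale_range: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if len(self.provenance) != self.matrix.shape[1]:
            raise ValueError("provenance length must equal column count")

    @property
    def has_duplicate_columns(self) -> bool:
        return len(set(self.provenance)) < len(self.provenance)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the fitted min-max scaling to rows laid out like this matrix."""
        if self.scale_min is None:
            raise ValueError("scaling not fitted; call fit_scaling first")
        return (np.atleast_2d(X) - self.scale_min) / self.scale_range


def _block_columns(block) -> tuple[np.ndarray, list[ColumnProvenance]]:
    if isinstance(block, SpectraMatrix):
        name = "spectra"
        mat, lam, sensor = block.matrix, block.wavelengths, block.sensor
    elif isinstance(block, TextureBlock):
        name = block.parameter
        mat, lam, sensor = block.matrix, block.wavelengths, block.sensor
    else:
        raise TypeError(f"cannot fuse block of type {type(block).__name__}")
    prov = [ColumnProvenance(sensor, name, j, float(lam[j])) for j in range(mat.shape[1])]
    return mat, prov


def pixel_fuse(*blocks) -> FusedMatrix:
    """Column-wise concatenation of full blocks (no column dropped)."""
    if len(blocks) < 2:
        raise ValueError("pixel fusion needs at least two blocks")
    mats, prov = [], []
    n_rows = None
    for b in blocks:
        mat, p = _block_columns(b)
        if mat.shape[1] == 0 or mat.shape[0] == 0:
            raise ValueError("cannot fuse an empty block")
        if n_rows is None:
            n_rows = mat.shape[0]
        elif mat.shape[0] != n_rows:
            raise ValueError(f"row mismatch: {mat.shape[0]} vs {n_rows}")
        mats.append(mat)
        prov.extend(p)
    fused = FusedMatrix(np.concatenate(mats, axis=1), tuple(prov), "pixel")
    if fused.has_duplicate_columns:
        logger.warning("pixel_fuse: duplicated columns detected in provenance")
    return fused


def feature_fuse(blocks: list[tuple[object, FeatureSelection]]) -> FusedMatrix:
    """Concatenate blocks restricted to their selected columns."""
    if not blocks:
        raise ValueError("feature fusion needs at least one (block, selection) pair")
    mats, prov = [], []
    n_rows = None
    for block, sel in blocks:
        mat, p = _block_columns(block)
        if sel is None or sel.indices.size == 0:
            raise ValueError("empty selection for a fused block")
        if mat.shape[1] != sel.n_columns:
            raise ValueError("selection was made on a block of different width")
        if n_rows is None:
            n_rows = mat.shape[0]
        elif mat.shape[0] != n_rows:
            raise ValueError(f"row mismatch: {mat.shape[0]} vs {n_rows}")
        mats.append(mat[:, sel.indices])
        prov.extend(p[j] for j in sel.indices)
    return FusedMatrix(np.concatenate(mats, axis=1), tuple(prov), "feature")


def fit_scaling(fused: FusedMatrix, calibration_rows) -> FusedMatrix:
    """Fit per-column min-max scaling on calibration rows.

    Constant columns get range 1 (so they map to 0), logged.  Returns a new
    FusedMatrix whose ``matrix`` is the scaled version of the input and whose
    ``transform`` maps any compatible rows with the same fitted context.
    """
    cal = np.asarray(calibration_rows)
    if cal.size < 2:
        raise ValueError("need at least 2 calibration rows to fit scaling")
    sub = fused.matrix[cal]
    lo = sub.min(axis=0)
    rng_ = sub.max(axis=0) - lo
    const = rng_ <= 0
    if const.any():
        logger.warning("fit_scaling: %d constant columns (range set to 1)", int(const.sum()))
        rng_ = np.where(const, 1.0, rng_)
    scaled = replace(
        fused,
        matrix=(fused.matrix - lo) / rng_,
        scale_min=lo,
        scale_range=rng_,
    )
    return scaled
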