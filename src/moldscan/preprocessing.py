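"""Chemometric spectral pretreatment: smooth, MSC, detrend, mean centering.

Treatments compose as "smooth-then-X" chains named by hyphen-joined recipe
strings ("smooth-msc", "smooth-detrend", "smooth-center").  Fit-dependent
treatments (the MSC reference spectrum, centering column means) are fitted
on the calibration subset and frozen, so prediction rows are transformed
with calibration context rather than their own statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_MSC_SLOPE_EPS = 1e-8

TREATMENTS = ("smooth", "msc", "detrend", "center")


@dataclass
class SpectraMatrix:
    """samples x bands mean-reflectance matrix with preprocessing provenance.

    ``provenance`` is the append-only list of applied treatment names (with
    parameters); ``context`` captures fitted state (``msc_reference``,
    ``center_means``) so the identical transform can be replayed on new rows.
    """

    matrix: np.ndarray
    wavelengths: np.ndarray
    sensor: str = ""
    provenance: tuple[str, ...] = ()
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.matrix.shape[1] != self.wavelengths.size:
            raise ValueError("matrix width must match wavelength axis length")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("spectra contain non-finite entries")

    @property
    def recipe(self) -> str:
        return "-".join(self.provenance) if self.provenance else "original"

    def _derive(self, matrix: np.ndarray, step: str, **ctx) -> "SpectraMatrix":
        return SpectraMatrix(
            matrix,
            self.wavelengths,
            self.sensor,
            self.provenance + (step,),
            {**self.context, **ctx},
        )


def smooth(spectra: SpectraMatrix, window: int = 9) -> SpectraMatrix:
    """Centered moving-average smoothing with shrinking symmetric edge windows.

    The 9-point default follows the usual chemometric noise filter.  At band
    i the half-width shrinks to min(h, i, B-1-i) so the matrix keeps its full
    width and a linear spectrum passes through unchanged everywhere.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window < 3 or window > spectra.matrix.shape[1]:
        raise ValueError("smoothing window must be in [3, n_bands]")
    X = spectra.matrix
    n_bands = X.shape[1]
    half = window // 2
    idx = np.arange(n_bands)
    h = np.minimum(half, np.minimum(idx, n_bands - 1 - idx))
    csum = np.cumsum(X, axis=1)
    csum = np.concatenate([np.zeros((X.shape[0], 1)), csum], axis=1)
    out = (csum[:, idx + h + 1] - csum[:, idx - h]) / (2 * h + 1)
    return spectra._derive(out, "smooth")


def msc(spectra: SpectraMatrix, reference: np.ndarray | None = None) -> SpectraMatrix:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed on the reference (x ~ a + b*ref) and replaced by
    (x - a) / b, removing per-sample additive offset and multiplicative
    scatter.  The reference defaults to the mean spectrum of the given rows
    (the calibration set) and is stored in context for reuse.  Rows with
    near-zero slope are passed through unchanged.
    """
    X = spectra.matrix
    if X.shape[1] < 2:
        raise ValueError("MSC needs at least 2 bands")
    ref = np.asarray(
        spectra.context.get("msc_reference") if reference is None else reference
    )
    if reference is None and "msc_reference" not in spectra.context:
        ref = X.mean(axis=0)
    ref = ref.astype(np.float64)
    if ref.size != X.shape[1]:
        raise ValueError("MSC reference length must match band count")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    b = (X @ ref_c) / denom
    a = X.mean(axis=1) - b * ref.mean()
    out = np.empty_like(X)
    ok = np.abs(b) >= _MSC_SLOPE_EPS
    out[ok] = (X[ok] - a[ok, None]) / b[ok, None]
    out[~ok] = X[~ok]
    return spectra._derive(out, "msc", msc_reference=ref.copy())


def detrend(spectra: SpectraMatrix) -> SpectraMatrix:
    """Subtract each row's least-squares line of reflectance on wavelength."""
    lam = spectra.wavelengths
    if np.unique(lam).size < 2:
        raise ValueError("detrend needs at least 2 distinct wavelengths")
    X = spectra.matrix
    lam_c = lam - lam.mean()
    slope = (X @ lam_c) / float(lam_c @ lam_c)
    intercept = X.mean(axis=1)
    out = X - intercept[:, None] - slope[:, None] * lam_c[None, :]
    return spectra._derive(out, "detrend")


def center(spectra: SpectraMatrix, fitted_means: np.ndarray | None = None) -> SpectraMatrix:
    """Column (variable-wise) mean centering.

    Means default to this matrix's own column means (calibration fit) and are
    stored in context; pass calibration means to center prediction rows
    without leakage.
    """
    X = spectra.matrix
    if fitted_means is None:
        fitted_means = np.asarray(spectra.context.get("center_means", X.mean(axis=0)))
    fitted_means = np.asarray(fitted_means, dtype=np.float64)
    if fitted_means.size != X.shape[1]:
        raise ValueError("fitted means length must match band count")
    return spectra._derive(X - fitted_means[None, :], "center", center_means=fitted_means.copy())


def chain(
    spectra: SpectraMatrix,
    recipe: str | list[str],
    context: dict | None = None,
    smooth_window: int = 9,
) -> SpectraMatrix:
    """Apply an ordered treatment recipe, e.g. ``"smooth-detrend"``.

    When ``context`` from a previous (calibration) run is supplied, its
    fitted MSC reference / centering means are reused so prediction rows get
    the identical transform.
    """
    steps = recipe.split("-") if isinstance(recipe, str) else list(recipe)
    for s in steps:
        if s not in TREATMENTS:
            raise ValueError(f"unknown treatment {s!r}")
    if "smooth" in steps and steps[0] != "smooth":
        raise ValueError("smooth must come first in a recipe")
    if context:
        spectra = replace(spectra, context={**spectra.context, **context})
    for s in steps:
        if s == "smooth":
            spectra = smooth(spectra, smooth_window)
        elif s == "msc":
            spectra = msc(spectra)
        elif s == "detrend":
            spectra = detrend(spectra)
        else:
            spectra = center(spectra)
    return spectra
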