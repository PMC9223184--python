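"""Wavelength/variable selection: VCPA, IRIV and the hybrid mVCPA-IRIV.

All three selectors share one fitness function: the stratified k-fold
cross-validated misclassification rate of a PLS-DA model restricted to the
candidate column subset (components chosen by CV, capped at
min(10, n_vars, n-1)).  The final classification models use SVM; PLS-DA is
used inside the selectors for speed, following the selectors' original
formulations.

* VCPA: binary-matrix sampling draws random variable combinations over the
  current pool; the inclusion frequency of each variable among the best
  sigma*K combinations ranks the pool, which shrinks along an exponentially
  decreasing schedule down to L variables; the best of all 2^L - 1 subsets
  of the final pool is returned.
* IRIV: per round, a random inclusion matrix is scored and, for each
  variable, scores of combinations including it are compared with the paired
  pseudo-population obtained by flipping that variable; variables whose
  inclusion does not improve mean fitness are dropped (strong/weak
  informative kept, uninformative/interfering removed), iterating until
  stable, followed by backward elimination.
* mVCPA-IRIV: VCPA's frequency-ranking phase shrinks to an intermediate
  pool, then IRIV runs on that pool.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import mannwhitneyu

from ._plsda import cv_error, cv_error_batch
from .imaging import LEVELS

logger = logging.getLogger(__name__)


@dataclass
class FitnessSpec:
    """Evaluator configuration for selector fitness."""

    evaluator: str = "plsda"
    folds: int = 5
    max_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.evaluator != "plsda":
            raise ValueError(f"unknown fitness evaluator {self.evaluator!r}")


@dataclass
class VcpaParams:
    """VCPA budgets: EDF schedule length, BMS runs, elite fraction, final pool."""

    edf_iterations: int = 50
    bms_runs: int = 500
    top_fraction: float = 0.1
    final_pool: int = 14

    @classmethod
    def reduced(cls) -> "VcpaParams":
        """Scaled-down budgets for desk-scale runs."""
        return cls(edf_iterations=15, bms_runs=100)


@dataclass
class IrivParams:
    """IRIV budgets: inclusion-matrix rows, inclusion probability, test level."""

    rows: int = 500
    inclusion_prob: float = 0.5
    alpha: float = 0.05
    max_rounds: int = 20

    @classmethod
    def reduced(cls) -> "IrivParams":
        return cls(rows=100)


@dataclass
class FeatureSelection:
    """Result of one selector on one data block."""

    block_id: str
    algorithm: str
    indices: np.ndarray
    fitness_trace: list[float]
    seed: int
    n_columns: int
    wavelengths: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.indices = np.unique(np.asarray(self.indices, dtype=np.int64))
        if self.indices.size == 0:
            raise ValueError("empty selection")
        if self.indices.min() < 0 or self.indices.max() >= self.n_columns:
            raise ValueError("selected indices outside block width")

    def to_json(self) -> str:
        d = {
            "block_id": self.block_id,
            "algorithm": self.algorithm,
            "indices": self.indices.tolist(),
            "fitness_trace": list(self.fitness_trace),
            "seed": self.seed,
            "n_columns": self.n_columns,
            "wavelengths": None if self.wavelengths is None else list(map(float, self.wavelengths)),
            "params": self.params,
            "flags": self.flags,
        }
        return json.dumps(d, indent=1)


def encode_labels(y) -> np.ndarray:
    """Map level labels to integer codes in canonical severity order."""
    y = np.asarray(y)
    classes = [lv for lv in LEVELS if lv in set(y)] or sorted(set(y))
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in y], dtype=np.int64)


def stratified_fold_ids(yi: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Per-class round-robin fold assignment after a class-wise shuffle."""
    fold_id = np.empty(yi.size, dtype=np.int64)
    for c in np.unique(yi):
        idx = np.flatnonzero(yi == c)
        rng.shuffle(idx)
        fold_id[idx] = np.arange(idx.size) % n_folds
    return fold_id


def _prepare(X, y, spec: FitnessSpec):
    X = np.ascontiguousarray(X, dtype=np.float64)
    yi = encode_labels(y)
    m = int(yi.max()) + 1
    Y = np.zeros((yi.size, m))
    Y[np.arange(yi.size), yi] = 1.0
    rng = np.random.default_rng([spec.seed, 7919])
    fold_id = stratified_fold_ids(yi, spec.folds, rng)
    return X, Y, yi, fold_id


def fitness(X, y, subset, spec: FitnessSpec | None = None) -> float:
    """CV misclassification rate of the fitness evaluator on X[:, subset]."""
    spec = spec or FitnessSpec()
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise ValueError("empty subset")
    if np.unique(np.asarray(y)).size < 2:
        raise ValueError("need at least 2 classes")
    X, Y, yi, fold_id = _prepare(X, y, spec)
    return float(cv_error(X, Y, yi, subset, fold_id, spec.folds, spec.max_components))


def _score_batch(X, Y, yi, fold_id, spec, subsets: list[np.ndarray]) -> np.ndarray:
    sizes = np.array([s.size for s in subsets], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    flat = np.concatenate(subsets).astype(np.int64) if subsets else np.empty(0, np.int64)
    return cv_error_batch(X, Y, yi, flat, offsets, fold_id, spec.folds, spec.max_components)


def _bms_rows(rng: np.random.Generator, k_runs: int, pool_size: int, p_incl: float = 0.5) -> np.ndarray:
    """Binary matrix sampling rows, each with at least 2 included variables."""
    A = rng.random((k_runs, pool_size)) < p_incl
    for j in range(k_runs):
        deficit = 2 - int(A[j].sum())
        if deficit > 0:
            off = np.flatnonzero(~A[j])
            A[j, rng.choice(off, size=deficit, replace=False)] = True
    return A


def _edf_schedule(p: int, L: int, n_iter: int) -> np.ndarray:
    """Exponentially decreasing pool sizes, reaching L at the last iteration."""
    i = np.arange(1, n_iter + 1)
    sizes = np.round(p * np.exp(-i * np.log(p / L) / n_iter)).astype(int)
    return np.maximum(sizes, L)


def _vcpa_edf_phase(X, Y, yi, fold_id, spec, params, rng, target_pool: int):
    """Shared VCPA frequency-ranking phase; shrinks the pool to target_pool.

    Returns (pool, trace, best_subset, best_err).
    """
    p = X.shape[1]
    pool = np.arange(p, dtype=np.int64)
    schedule = _edf_schedule(p, target_pool, params.edf_iterations)
    trace: list[float] = []
    best_err = np.inf
    best_subset = pool.copy()
    for target in schedule:
        if pool.size <= target_pool:
            break
        if pool.size < 2:
            logger.warning("VCPA pool collapsed below 2; stopping early")
            break
        A = _bms_rows(rng, params.bms_runs, pool.size)
        subsets = [pool[A[j]] for j in range(params.bms_runs)]
        errs = _score_batch(X, Y, yi, fold_id, spec, subsets)
        j_best = int(np.argmin(errs))
        if errs[j_best] < best_err:
            best_err = float(errs[j_best])
            best_subset = subsets[j_best].copy()
        trace.append(min(best_err, trace[-1]) if trace else best_err)
        n_top = max(1, int(round(params.top_fraction * params.bms_runs)))
        top = np.argsort(errs, kind="stable")[:n_top]
        freq = A[top].sum(axis=0)
        if target < pool.size:
            # keep highest-frequency variables; ties favor lower column index
            order = np.lexsort((np.arange(pool.size), -freq))
            pool = np.sort(pool[order[:target]])
    return pool, trace, best_subset, best_err


def vcpa(X, y, spec: FitnessSpec | None = None, params: VcpaParams | None = None,
         block_id: str = "", wavelengths=None) -> FeatureSelection:
    """Variable combination population analysis."""
    spec = spec or FitnessSpec()
    params = params or VcpaParams()
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] < params.final_pool:
        raise ValueError("block narrower than the VCPA final pool")
    Xc, Y, yi, fold_id = _prepare(X, y, spec)
    rng = np.random.default_rng([spec.seed, 101])
    pool, trace, best_subset, best_err = _vcpa_edf_phase(
        Xc, Y, yi, fold_id, spec, params, rng, params.final_pool
    )
    if pool.size >= 2:
        # exhaustive search over all nonempty subsets of the final pool
        L = pool.size
        subsets = []
        for code in range(1, 2**L):
            bits = np.flatnonzero([(code >> b) & 1 for b in range(L)])
            subsets.append(pool[bits])
        errs = _score_batch(Xc, Y, yi, fold_id, spec, subsets)
        sizes = np.array([s.size for s in subsets])
        # argmin with ties broken toward smaller subsets, then packing order;
        # the returned selection always comes from the final pool (<= L vars)
        order = np.lexsort((np.arange(len(subsets)), sizes, errs))
        j = order[0]
        best_subset, best_err = subsets[j], min(float(errs[j]), best_err)
        trace.append(min(best_err, trace[-1]) if trace else best_err)
    return FeatureSelection(
        block_id=block_id, algorithm="vcpa", indices=best_subset,
        fitness_trace=trace, seed=spec.seed, n_columns=X.shape[1],
        wavelengths=None if wavelengths is None else np.asarray(wavelengths)[np.unique(best_subset)],
        params=asdict(params),
    )


def _backward_eliminate(Xc, Y, yi, fold_id, spec, retained: np.ndarray, trace: list[float]):
    cur = float(cv_error(Xc, Y, yi, retained, fold_id, spec.folds, spec.max_components))
    trace.append(min(cur, trace[-1]) if trace else cur)
    while retained.size > 1:
        candidates = [np.delete(retained, k) for k in range(retained.size)]
        errs = _score_batch(Xc, Y, yi, fold_id, spec, candidates)
        k = int(np.argmin(errs))
        if errs[k] < cur:
            retained = candidates[k]
            cur = float(errs[k])
            trace.append(min(cur, trace[-1]) if trace else cur)
        else:
            break
    return retained, cur


def iriv(X, y, spec: FitnessSpec | None = None, params: IrivParams | None = None,
         block_id: str = "", wavelengths=None) -> FeatureSelection:
    """Iteratively retains informative variables."""
    spec = spec or FitnessSpec()
    params = params or IrivParams()
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] < 2:
        raise ValueError("IRIV needs at least 2 columns")
    Xc, Y, yi, fold_id = _prepare(X, y, spec)
    rng = np.random.default_rng([spec.seed, 202])
    retained = np.arange(X.shape[1], dtype=np.int64)
    trace: list[float] = []
    flags: list[str] = []

    for rnd in range(params.max_rounds):
        p_r = retained.size
        if p_r < 2:
            break
        A = _bms_rows(rng, params.rows, p_r, params.inclusion_prob)
        base_subsets = [retained[A[j]] for j in range(params.rows)]
        P0 = _score_batch(Xc, Y, yi, fold_id, spec, base_subsets)
        trace.append(float(P0.min()) if not trace else min(float(P0.min()), trace[-1]))

        incl = np.empty((params.rows, p_r))
        excl = np.empty((params.rows, p_r))
        for i in range(p_r):
            Af = A.copy()
            Af[:, i] = ~Af[:, i]
            # flipping may empty a row; guarantee at least one variable
            flipped = []
            for j in range(params.rows):
                cols = retained[Af[j]]
                flipped.append(cols if cols.size else retained[[i]])
            P1 = _score_batch(Xc, Y, yi, fold_id, spec, flipped)
            has = A[:, i]
            incl[:, i] = np.where(has, P0, P1)
            excl[:, i] = np.where(has, P1, P0)

        dmean = excl.mean(axis=0) - incl.mean(axis=0)
        pvals = mannwhitneyu(incl, excl, axis=0, alternative="two-sided").pvalue
        keep = dmean > 0  # strongly (p < alpha) or weakly informative
        n_drop = int((~keep).sum())
        logger.info(
            "IRIV round %d: %d vars, dropped %d (strong %d, weak %d)",
            rnd + 1, p_r, n_drop,
            int((keep & (pvals < params.alpha)).sum()),
            int((keep & (pvals >= params.alpha)).sum()),
        )
        if n_drop == 0:
            break
        retained = retained[keep]

    if retained.size == 0:
        singles = [np.array([i], dtype=np.int64) for i in range(X.shape[1])]
        errs = _score_batch(Xc, Y, yi, fold_id, spec, singles)
        retained = np.array([int(np.argmin(errs))], dtype=np.int64)
        flags.append("all variables dropped; best single variable returned")
        trace.append(float(errs.min()))
    else:
        retained, _ = _backward_eliminate(Xc, Y, yi, fold_id, spec, retained, trace)

    return FeatureSelection(
        block_id=block_id, algorithm="iriv", indices=retained,
        fitness_trace=trace, seed=spec.seed, n_columns=X.shape[1],
        wavelengths=None if wavelengths is None else np.asarray(wavelengths)[np.unique(retained)],
        params=asdict(params), flags=flags,
    )


def mvcpa_iriv(X, y, spec: FitnessSpec | None = None,
               vcpa_params: VcpaParams | None = None,
               iriv_params: IrivParams | None = None,
               intermediate_pool: int = 50,
               block_id: str = "", wavelengths=None) -> FeatureSelection:
    """Hybrid selector: VCPA frequency-ranking phase, then IRIV on the pool."""
    spec = spec or FitnessSpec()
    vcpa_params = vcpa_params or VcpaParams()
    iriv_params = iriv_params or IrivParams()
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] <= intermediate_pool:
        sel = iriv(X, y, spec, iriv_params, block_id=block_id, wavelengths=wavelengths)
        return FeatureSelection(
            block_id=block_id, algorithm="mvcpa-iriv", indices=sel.indices,
            fitness_trace=sel.fitness_trace, seed=spec.seed, n_columns=X.shape[1],
            wavelengths=sel.wavelengths,
            params={"intermediate_pool": intermediate_pool, **sel.params},
            flags=sel.flags + ["block narrower than intermediate pool; reduces to IRIV"],
        )
    Xc, Y, yi, fold_id = _prepare(X, y, spec)
    rng = np.random.default_rng([spec.seed, 101])
    pool, trace, _, _ = _vcpa_edf_phase(Xc, Y, yi, fold_id, spec, vcpa_params, rng, intermediate_pool)
    pool = pool[:intermediate_pool]
    sel = iriv(X[:, pool], y, spec, iriv_params)
    indices = pool[sel.indices]
    return FeatureSelection(
        block_id=block_id, algorithm="mvcpa-iriv", indices=indices,
        fitness_trace=trace + sel.fitness_trace, seed=spec.seed, n_columns=X.shape[1],
        wavelengths=None if wavelengths is None else np.asarray(wavelengths)[np.unique(indices)],
        params={"intermediate_pool": intermediate_pool, **asdict(vcpa_params)},
        flags=sel.flags,
    )
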