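"""Compiled PLS-DA cross-validation used as the selector fitness function.

Variable selection evaluates tens of thousands of column subsets, each with
a stratified k-fold cross-validated PLS-DA misclassification rate, so the
inner loop is compiled with numba.  The PLS fit is SIMPLS on mean-centered
X and one-hot Y; class assignment uses nearest-training-class-centroid
decoding in the predicted-score space (the "centroid distance" rule common
in chemometrics packages), which stays informative when the ordered class
means are nearly collinear — the typical geometry of severity grades.
Predictions for every component count 1..A are produced in a single pass
and the reported CV error is the minimum over component counts (the usual
chemometric component choice, at no extra model fits).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _power_iter(M, n_iter=60):
    """Dominant eigenvector of a small symmetric PSD matrix (deterministic).

    Scalar loops on purpose: M is tiny (classes x classes) and this sits in
    the innermost hot path, so BLAS dispatch would dominate the cost.
    """
    m = M.shape[0]
    # graded (non-uniform) start: a uniform vector is exactly orthogonal to
    # the dominant eigenvector in the two-class case, where the one-hot
    # residual columns are anticorrelated
    q = np.empty(m)
    nrm0 = 0.0
    for i in range(m):
        q[i] = 1.0 + 0.01 * i
        nrm0 += q[i] * q[i]
    nrm0 = np.sqrt(nrm0)
    for i in range(m):
        q[i] /= nrm0
    q2 = np.empty(m)
    for _ in range(n_iter):
        for i in range(m):
            s = 0.0
            for j in range(m):
                s += M[i, j] * q[j]
            q2[i] = s
        nrm = 0.0
        for i in range(m):
            nrm += q2[i] * q2[i]
        nrm = np.sqrt(nrm)
        if nrm < 1e-250:
            break
        delta = 0.0
        for i in range(m):
            v = q2[i] / nrm
            delta += abs(v - q[i])
            q[i] = v
        if delta < 1e-12:
            break
    return q


@njit(cache=True)
def _cv_error_cols(X, Y, yi, cols, fold_id, n_folds, max_comp):
    """Min-over-components CV misclassification rate of PLS-DA on X[:, cols]."""
    n = X.shape[0]
    k = cols.shape[0]
    m = Y.shape[1]
    A = max_comp if max_comp < k else k

    Xs = np.empty((n, k))
    for r in range(n):
        for c in range(k):
            Xs[r, c] = X[r, cols[c]]

    errs = np.zeros(A, dtype=np.int64)
    for f in range(n_folds):
        ntr = 0
        for r in range(n):
            if fold_id[r] != f:
                ntr += 1
        nval = n - ntr
        if nval == 0 or ntr <= 1:
            continue
        Xtr = np.empty((ntr, k))
        Ytr = np.empty((ntr, m))
        Xval = np.empty((nval, k))
        yval = np.empty(nval, dtype=np.int64)
        it = 0
        iv = 0
        for r in range(n):
            if fold_id[r] != f:
                for c in range(k):
                    Xtr[it, c] = Xs[r, c]
                for c in range(m):
                    Ytr[it, c] = Y[r, c]
                it += 1
            else:
                for c in range(k):
                    Xval[iv, c] = Xs[r, c]
                yval[iv] = yi[r]
                iv += 1
        xmean = np.empty(k)
        for c in range(k):
            s = 0.0
            for r in range(ntr):
                s += Xtr[r, c]
            xmean[c] = s / ntr
        ymean = np.empty(m)
        for c in range(m):
            s = 0.0
            for r in range(ntr):
                s += Ytr[r, c]
            ymean[c] = s / ntr
        Xc = Xtr - xmean
        Yc = Ytr - ymean
        Xvc = Xval - xmean

        ytr = np.empty(ntr, dtype=np.int64)
        it = 0
        for r in range(n):
            if fold_id[r] != f:
                ytr[it] = yi[r]
                it += 1
        ncls = np.zeros(m, dtype=np.int64)
        for r in range(ntr):
            ncls[ytr[r]] += 1

        S = Xc.T @ Yc
        V = np.zeros((k, A))
        # cumulative predicted scores for validation AND training rows; class
        # assignment is by nearest training-class centroid in score space
        # (robust when ordered class means are collinear, unlike argmax)
        Yhat = np.empty((nval, m))
        for r in range(nval):
            for c in range(m):
                Yhat[r, c] = ymean[c]
        Yhat_tr = np.empty((ntr, m))
        for r in range(ntr):
            for c in range(m):
                Yhat_tr[r, c] = ymean[c]
        centroids = np.empty((m, m))
        alive = True
        for a in range(A):
            if alive:
                q = _power_iter(S.T @ S)
                w = S @ q
                t = Xc @ w
                tnorm = np.sqrt((t * t).sum())
                if tnorm < 1e-10:
                    alive = False
                else:
                    t = t / tnorm
                    w = w / tnorm
                    p_load = Xc.T @ t
                    qq = Yc.T @ t
                    v = p_load.copy()
                    for j in range(a):
                        proj = 0.0
                        for r in range(k):
                            proj += V[r, j] * p_load[r]
                        for r in range(k):
                            v[r] -= V[r, j] * proj
                    vnorm = np.sqrt((v * v).sum())
                    if vnorm < 1e-10:
                        alive = False
                    else:
                        v = v / vnorm
                        for r in range(k):
                            V[r, a] = v[r]
                        S = S - np.outer(v, v @ S)
                        tval = Xvc @ w
                        for r in range(nval):
                            for c in range(m):
                                Yhat[r, c] += tval[r] * qq[c]
                        for r in range(ntr):
                            for c in range(m):
                                Yhat_tr[r, c] += t[r] * qq[c]
            # class centroids of training scores with the first a+1 components
            for c in range(m):
                for d in range(m):
                    centroids[c, d] = 0.0
            for r in range(ntr):
                for d in range(m):
                    centroids[ytr[r], d] += Yhat_tr[r, d]
            for c in range(m):
                if ncls[c] > 0:
                    for d in range(m):
                        centroids[c, d] /= ncls[c]
            # count misclassifications by nearest centroid
            for r in range(nval):
                besti = 0
                bestv = 1e300
                for c in range(m):
                    dist = 0.0
                    for d in range(m):
                        diff = Yhat[r, d] - centroids[c, d]
                        dist += diff * diff
                    if dist < bestv:
                        bestv = dist
                        besti = c
                if besti != yval[r]:
                    errs[a] += 1
    best = errs[0]
    for a in range(1, A):
        if errs[a] < best:
            best = errs[a]
    return best / n


@njit(cache=True)
def cv_error_batch(X, Y, yi, flat, offsets, fold_id, n_folds, max_comp):
    """CV error for many column subsets packed as flat indices + offsets."""
    n_sub = offsets.shape[0] - 1
    out = np.empty(n_sub)
    for s in range(n_sub):
        cols = flat[offsets[s] : offsets[s + 1]]
        out[s] = _cv_error_cols(X, Y, yi, cols, fold_id, n_folds, max_comp)
    return out


def cv_error(X, Y, yi, cols, fold_id, n_folds, max_comp):
    """Single-subset convenience wrapper around the compiled kernel."""
    return _cv_error_cols(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(Y, dtype=np.float64),
        np.ascontiguousarray(yi, dtype=np.int64),
        np.ascontiguousarray(cols, dtype=np.int64),
        np.ascontiguousarray(fold_id, dtype=np.int64),
        n_folds,
        max_comp,
    )
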