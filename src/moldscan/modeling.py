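"""Stratified splitting, classifier training and evaluation.

The experiment design is balanced (60 samples per mold level); each level is
randomly partitioned 3:1 into calibration and prediction rows.  Three
classifiers are supported: SVM with an RBF kernel and a log2 grid search
over (C, gamma), random forest with 50 trees, and KNN with CV-selected
neighbor count and distance metric.  Reports carry calibration/prediction
accuracy (percent), per-class accuracy, the confusion matrix in fixed
healthy-to-severe order, and the count of moldy samples predicted healthy —
the safety-critical failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .imaging import LEVELS

DEFAULT_SVM_GRID = {
    "C": [2.0**e for e in range(-8, 9)],
    "gamma": [2.0**e for e in range(-8, 9)],
}
DEFAULT_KNN_GRID = {
    "n_neighbors": list(range(1, 16, 2)),
    "metric": ["euclidean", "cityblock"],
}


@dataclass
class SplitAssignment:
    calibration: np.ndarray
    prediction: np.ndarray
    per_class: dict[str, tuple[int, int]]
    seed: int


@dataclass
class ClassifierReport:
    classifier: str
    hyperparameters: dict
    calibration_accuracy: float
    prediction_accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: np.ndarray
    class_order: tuple[str, ...]
    moldy_as_healthy: int
    seed: int

    @property
    def overfitting_gap(self) -> float:
        return abs(self.calibration_accuracy - self.prediction_accuracy)

    def summary_row(self) -> dict:
        return {
            "classifier": self.classifier,
            "calibration_accuracy": round(self.calibration_accuracy, 2),
            "prediction_accuracy": round(self.prediction_accuracy, 2),
            "overfitting_gap": round(self.overfitting_gap, 2),
            "moldy_as_healthy": self.moldy_as_healthy,
        }


def stratified_split(labels, seed: int, ratio: tuple[int, int] = (3, 1)) -> SplitAssignment:
    """Per-class random 3:1 partition into calibration and prediction rows.

    Classes not divisible by the ratio floor the prediction count and give
    the remainder to calibration.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng([seed, 31])
    cal, pred, per_class = [], [], {}
    for cls in [lv for lv in LEVELS if lv in set(labels)] or sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        rng.shuffle(idx)
        n_pred = idx.size * ratio[1] // sum(ratio)
        n_pred = max(1, n_pred)
        pred.append(np.sort(idx[:n_pred]))
        cal.append(np.sort(idx[n_pred:]))
        per_class[cls] = (idx.size - n_pred, n_pred)
    return SplitAssignment(
        calibration=np.sort(np.concatenate(cal)),
        prediction=np.sort(np.concatenate(pred)),
        per_class=per_class,
        seed=seed,
    )


def _class_order(y) -> tuple[str, ...]:
    present = set(np.asarray(y))
    ordered = [lv for lv in LEVELS if lv in present]
    ordered += sorted(present - set(ordered))
    return tuple(ordered)


def evaluate(model, X, y, class_order: tuple[str, ...] | None = None) -> dict:
    """Confusion matrix (healthy first), per-class and overall accuracy.

    ``moldy_as_healthy`` counts non-healthy samples predicted as the first
    class — the misgrade a grading system must not make.
    """
    y = np.asarray(y)
    order = class_order or _class_order(y)
    lut = {c: i for i, c in enumerate(order)}
    pred = np.asarray(model.predict(X))
    unknown = set(y) - set(order)
    if unknown:
        raise ValueError(f"labels outside training classes: {unknown}")
    k = len(order)
    conf = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y, pred):
        conf[lut[t], lut[p]] += 1
    per_class = {
        c: 100.0 * conf[i, i] / conf[i].sum() if conf[i].sum() else float("nan")
        for i, c in enumerate(order)
    }
    overall = 100.0 * np.trace(conf) / conf.sum()
    moldy_as_healthy = int(conf[1:, 0].sum()) if order and order[0] == "healthy" else 0
    return {
        "confusion": conf,
        "class_order": order,
        "per_class_accuracy": per_class,
        "accuracy": float(overall),
        "moldy_as_healthy": moldy_as_healthy,
    }


def _report(name, model, params, X, y, split, seed) -> ClassifierReport:
    order = _class_order(y[split.calibration])
    cal = evaluate(model, X[split.calibration], y[split.calibration], order)
    pred = evaluate(model, X[split.prediction], y[split.prediction], order)
    return ClassifierReport(
        classifier=name,
        hyperparameters=params,
        calibration_accuracy=cal["accuracy"],
        prediction_accuracy=pred["accuracy"],
        per_class_accuracy=pred["per_class_accuracy"],
        confusion=pred["confusion"],
        class_order=order,
        moldy_as_healthy=pred["moldy_as_healthy"],
        seed=seed,
    )


def train_svm(X, y, split: SplitAssignment, grid: dict | None = None,
              folds: int = 5, seed: int = 0):
    """RBF-kernel SVM with cross-validated grid search over (C, gamma)."""
    X, y = np.asarray(X, dtype=np.float64), np.asarray(y)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(SVC(kernel="rbf"), grid or DEFAULT_SVM_GRID, cv=cv, n_jobs=1)
    gs.fit(X[split.calibration], y[split.calibration])
    model = gs.best_estimator_
    return model, _report("svm", model, dict(gs.best_params_), X, y, split, seed)


def train_rf(X, y, split: SplitAssignment, n_trees: int = 50, seed: int = 0):
    """Random forest with a fixed number of trees (no grid search)."""
    X, y = np.asarray(X, dtype=np.float64), np.asarray(y)
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(X[split.calibration], y[split.calibration])
    return model, _report("rf", model, {"n_estimators": n_trees}, X, y, split, seed)


def train_knn(X, y, split: SplitAssignment, grid: dict | None = None,
              folds: int = 5, seed: int = 0):
    """KNN with CV selection of the neighbor count and distance metric."""
    X, y = np.asarray(X, dtype=np.float64), np.asarray(y)
    grid = grid or DEFAULT_KNN_GRID
    if max(grid.get("n_neighbors", [1])) > split.calibration.size:
        raise ValueError("neighbor count exceeds calibration size")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(KNeighborsClassifier(), grid, cv=cv, n_jobs=1)
    gs.fit(X[split.calibration], y[split.calibration])
    model = gs.best_estimator_
    return model, _report("knn", model, dict(gs.best_params_), X, y, split, seed)
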