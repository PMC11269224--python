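"""Confusion-matrix metrics and the k-fold cross-validation harness.

With seizure = 1 as the positive class: TP counts correctly detected
seizure epochs, FN missed seizures, TN correctly rejected background, FP
false alarms. Metrics:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = recall = TP / (TP + FN)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * recall / (precision + recall)

A zero denominator yields metric 0 rather than NaN. Cross-validation uses
stratified folds by default (class proportions preserved; fold sizes differ
by at most one) and evaluates each fold's model at the fixed threshold the
classifier carries.
"""

from __future__ import annotations

import inspect
from dataclasses import asdict, dataclass
from typing import Callable, Iterable

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import DimensionError, ValidationError


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    fold_id: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_counts(truth: np.ndarray, pred: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) for binary labels with 1 = seizure."""
    truth = np.asarray(truth).astype(int).ravel()
    pred = np.asarray(pred).astype(int).ravel()
    if truth.shape != pred.shape:
        raise DimensionError(
            f"truth and pred lengths differ: {truth.shape} vs {pred.shape}"
        )
    if not np.isin(truth, (0, 1)).all() or not np.isin(pred, (0, 1)).all():
        raise ValidationError("labels must be binary in {0, 1}")
    tp = int(np.sum((truth == 1) & (pred == 1)))
    tn = int(np.sum((truth == 0) & (pred == 0)))
    fp = int(np.sum((truth == 0) & (pred == 1)))
    fn = int(np.sum((truth == 1) & (pred == 0)))
    return tp, tn, fp, fn


def metrics_from_counts(
    tp: int, tn: int, fp: int, fn: int, fold_id: int | None = None
) -> MetricsReport:
    """Accuracy, precision, sensitivity and F1 from confusion counts."""
    if min(tp, tn, fp, fn) < 0:
        raise ValidationError("confusion counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValidationError("confusion counts are all zero")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    sensitivity = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity > 0
        else 0.0
    )
    return MetricsReport(tp, tn, fp, fn, accuracy, precision, sensitivity, f1, fold_id)


def evaluate_predictions(
    truth: np.ndarray, pred: np.ndarray, fold_id: int | None = None
) -> MetricsReport:
    return metrics_from_counts(*confusion_counts(truth, pred), fold_id=fold_id)


def _call_factory(factory: Callable, seed: int):
    """Instantiate a model, passing ``seed`` only if the factory accepts it."""
    try:
        params = inspect.signature(factory).parameters
    except (TypeError, ValueError):
        params = {}
    if "seed" in params or any(
        p.kind is inspect.Parameter.VAR_KEYWORD for p in params.values()
    ):
        return factory(seed=seed)
    return factory()


def kfold_cross_validate(
    X,
    y=None,
    k: int = 5,
    model_factory: Callable = None,
    seed: int = 0,
    stratified: bool = True,
) -> list[MetricsReport]:
    """k-fold cross-validation of a classifier factory.

    ``X`` may be a :class:`~saegbls.eeg.FeatureTable` (then ``y`` is taken
    from it) or a plain feature matrix with labels ``y``. Folds are a
    disjoint cover with sizes differing by at most one; each fold's model is
    fitted on the remaining k-1 folds (any standardization happens inside
    ``fit`` on training data only) and scored on the held-out fold. The
    factory is called once per fold; if it accepts a ``seed`` keyword it
    receives a fold-specific seed derived from ``seed``.
    """
    if model_factory is None:
        raise ValidationError("a model_factory is required")
    if hasattr(X, "features") and hasattr(X, "labels"):
        y = X.labels
        X = X.features
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")

    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    reports = []
    for fold_id, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        if np.unique(y[train_idx]).size < 2:
            raise ValidationError(
                f"fold {fold_id}: a class is absent from the training folds"
            )
        fold_seed = (seed * 9973 + fold_id) % (2**31)
        model = _call_factory(model_factory, fold_seed)
        model.fit(X[train_idx], y[train_idx])
        pred = np.asarray(model.predict(X[test_idx])).astype(int).ravel()
        reports.append(evaluate_predictions(y[test_idx], pred, fold_id=fold_id))
    return reports


def summarize(reports: Iterable[MetricsReport], mode: str = "mean") -> dict:
    """Summary across folds.

    ``mean`` gives mean and standard deviation per metric; ``best`` the
    single best fold by accuracy (F1 as tie-break), matching best-1-fold
    reporting.
    """
    reports = list(reports)
    if not reports:
        raise ValidationError("no fold reports to summarize")
    metrics = ("accuracy", "precision", "sensitivity", "f1")
    if mode == "mean":
        out = {}
        for name in metrics:
            vals = np.array([getattr(r, name) for r in reports])
            out[name] = {"mean": float(vals.mean()), "sd": float(vals.std())}
        return out
    if mode == "best":
        best = max(reports, key=lambda r: (r.accuracy, r.f1))
        return best.to_dict()
    raise ValidationError(f"unknown summary mode {mode!r}")
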