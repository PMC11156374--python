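"""Subject-level classification with a repeated cross-validated linear SVM.

Each binary task (one patient group vs. healthy controls) uses the
eight connected-speech features jointly. Every iteration re-randomizes
a stratified k-fold split; within each fold the features are min-max
scaled with parameters fit on the training folds only (the test fold
may therefore land outside [0, 1] — by design, to avoid leakage), a
linear-kernel SVM is fit, and its continuous decision scores on the
held-out fold are pooled per iteration for the ROC AUC while the
thresholded predictions feed accuracy, precision, recall, F1 and UAR
(macro-average recall). Feature importance is the mean absolute SVM
coefficient over all folds and iterations, comparable across features
thanks to the prior min-max step. A separate protocol fits scaler and
SVM once on the full main sample and evaluates once on a disjoint
hold-out sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

METRICS = ("AUC", "accuracy", "precision", "recall", "F1", "UAR")


@dataclass
class ClassificationReport:
    metrics: dict[str, tuple[float, float]]  # name -> (mean, sd) over iterations
    importances: pd.Series  # mean |coefficient| per feature, descending
    iterations: int
    folds: int
    seed: int | None
    n_imputed: int = 0
    roc_points: pd.DataFrame | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "metrics": {k: {"mean": m, "sd": s} for k, (m, s) in self.metrics.items()},
            "feature_importance": self.importances.to_dict(),
            "iterations": self.iterations,
            "folds": self.folds,
            "seed": self.seed,
            "n_imputed": self.n_imputed,
        }


def _validate(X: np.ndarray, y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class input: need both patients and controls")
    if counts.min() < k:
        raise ValueError(f"k={k} folds exceed smallest class size {counts.min()}")


def _impute_train_median(X_tr: np.ndarray, X_te: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Replace NaNs by the training-fold median, column-wise."""
    n_missing = int(np.isnan(X_tr).sum() + np.isnan(X_te).sum())
    if n_missing:
        med = np.nanmedian(X_tr, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        X_tr = np.where(np.isnan(X_tr), med[None, :], X_tr)
        X_te = np.where(np.isnan(X_te), med[None, :], X_te)
    return X_tr, X_te, n_missing


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> dict[str, float]:
    return {
        "AUC": float(roc_auc_score(y_true, scores)),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "F1": float(f1_score(y_true, y_pred, zero_division=0)),
        "UAR": float(balanced_accuracy_score(y_true, y_pred)),
    }


def run_repeated_cv(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    *,
    k: int = 5,
    iterations: int = 1000,
    C: float = 1.0,
    seed: int | None = None,
) -> ClassificationReport:
    """Repeated stratified k-fold CV of a linear SVM; positive class = 1.

    Per iteration the out-of-fold decision scores are pooled for one
    AUC value, the pooled hard predictions give the other metrics; the
    report carries mean and SD over iterations and is fully reproducible
    from ``seed``.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.shape(X)[1])
    ]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _validate(X, y, k)

    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(iterations) % (2**31 - 1)

    per_iter = {m: np.empty(iterations) for m in METRICS}
    coef_sum = np.zeros(X.shape[1])
    n_coefs = 0
    n_imputed = 0

    for it in range(iterations):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(fold_seeds[it]))
        scores = np.empty(len(y))
        preds = np.empty(len(y), dtype=int)
        for tr_idx, te_idx in skf.split(X, y):
            X_tr, X_te, n_miss = _impute_train_median(X[tr_idx], X[te_idx])
            n_imputed += n_miss
            scaler = MinMaxScaler().fit(X_tr)
            X_tr = scaler.transform(X_tr)
            X_te = scaler.transform(X_te)
            clf = SVC(kernel="linear", C=C)
            clf.fit(X_tr, y[tr_idx])
            scores[te_idx] = clf.decision_function(X_te)
            preds[te_idx] = clf.predict(X_te)
            coef_sum += np.abs(clf.coef_.ravel())
            n_coefs += 1
        for name, val in _binary_metrics(y, preds, scores).items():
            per_iter[name][it] = val

    importances = pd.Series(coef_sum / n_coefs, index=feature_names).sort_values(ascending=False)
    metrics = {m: (float(v.mean()), float(v.std(ddof=1)) if iterations > 1 else 0.0)
               for m, v in per_iter.items()}
    return ClassificationReport(
        metrics=metrics,
        importances=importances,
        iterations=iterations,
        folds=k,
        seed=seed,
        n_imputed=n_imputed,
    )


def feature_importance(coefficients: np.ndarray, feature_names: Sequence[str]) -> pd.Series:
    """Mean absolute coefficient per feature over fitted linear models.

    ``coefficients`` has shape (n_models, n_features); only linear
    models expose such coefficients (non-linear kernels are rejected
    upstream by construction).
    """
    coefs = np.atleast_2d(np.asarray(coefficients, dtype=float))
    imp = np.abs(coefs).mean(axis=0)
    return pd.Series(imp, index=list(feature_names)).sort_values(ascending=False)


def generalizability_eval(
    X_train: pd.DataFrame | np.ndarray,
    y_train: Sequence[int],
    X_test: pd.DataFrame | np.ndarray,
    y_test: Sequence[int],
    *,
    train_ids: Sequence[str] | None = None,
    test_ids: Sequence[str] | None = None,
    C: float = 1.0,
) -> ClassificationReport:
    """Train once on the full main split, evaluate once on the hold-out.

    No cross-validation: scaler and SVM are fit on all training rows and
    applied to the disjoint test participants. Overlapping participant
    ids between the splits raise a leakage error.
    """
    if train_ids is not None and test_ids is not None:
        overlap = set(train_ids) & set(test_ids)
        if overlap:
            raise ValueError(f"participant leakage between splits: {sorted(overlap)}")
    feature_names = list(X_train.columns) if isinstance(X_train, pd.DataFrame) else [
        f"f{i}" for i in range(np.shape(X_train)[1])
    ]
    X_tr = np.asarray(X_train, dtype=float)
    X_te = np.asarray(X_test, dtype=float)
    y_tr = np.asarray(y_train, dtype=int)
    y_te = np.asarray(y_test, dtype=int)
    _validate(X_tr, y_tr, 2)

    X_tr, X_te, n_imputed = _impute_train_median(X_tr, X_te)
    scaler = MinMaxScaler().fit(X_tr)
    clf = SVC(kernel="linear", C=C)
    clf.fit(scaler.transform(X_tr), y_tr)
    X_te_s = scaler.transform(X_te)
    scores = clf.decision_function(X_te_s)
    preds = clf.predict(X_te_s)

    metrics = {m: (v, 0.0) for m, v in _binary_metrics(y_te, preds, scores).items()}
    importances = pd.Series(np.abs(clf.coef_.ravel()), index=feature_names).sort_values(
        ascending=False
    )
    return ClassificationReport(
        metrics=metrics,
        importances=importances,
        iterations=1,
        folds=1,
        seed=None,
        n_imputed=n_imputed,
    )


def roc_points(y_true: Sequence[int], scores: Sequence[float]) -> pd.DataFrame:
    """ROC curve coordinates (fpr, tpr, threshold) for plotting/export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(y_true, dtype=int), np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
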