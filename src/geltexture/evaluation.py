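"""Cross-validation harness and threshold-free metrics.

All models of one experiment share a single stratified 10-fold assignment
(random reshuffle, then near-equal folds), which is what makes the per-fold
metric matrix a valid blocked design for the Friedman test downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FoldResult",
    "make_folds",
    "auroc",
    "prf",
    "mean_roc",
    "run_comparison",
]


@dataclass
class FoldResult:
    model: str
    fold: int
    auroc: float
    precision: float
    recall: float
    f_measure: float
    n_features: int
    roc_points: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)


def make_folds(n: int, y: np.ndarray, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Stratified k-fold test-index arrays after a seeded reshuffle."""
    if n < k:
        raise ValueError("need at least k samples")
    y = np.asarray(y)
    if len(y) != n:
        raise ValueError("labels length != n")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(n), y)]
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        if len(np.unique(y[train])) < 2:
            raise ValueError("a class is absent from some training fold")
    return folds


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank/Mann-Whitney handling of ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUROC")
    return float(roc_auc_score(labels, scores))


def prf(scores, labels, threshold: float = 0.0) -> tuple[float, float, float]:
    """Precision, recall and F-measure at a decision threshold.

    Zero predicted positives yields precision 0 (flagged via a warning-free
    convention rather than NaN).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f


def mean_roc(curves: list[tuple[np.ndarray, np.ndarray]],
             grid_points: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """Vertical averaging of (FPR, TPR) curves on a fixed FPR grid."""
    if not curves:
        raise ValueError("need at least one curve")
    grid = np.linspace(0.0, 1.0, grid_points)
    tprs = []
    for fpr, tpr in curves:
        fpr = np.concatenate([[0.0], np.asarray(fpr, float), [1.0]])
        tpr = np.concatenate([[0.0], np.asarray(tpr, float), [1.0]])
        tprs.append(np.interp(grid, fpr, tpr))
    return grid, np.mean(tprs, axis=0)


def run_comparison(
    X: pd.DataFrame,
    y: np.ndarray,
    models: dict,
    folds: list[np.ndarray],
    threshold: float = 0.0,
) -> tuple[pd.DataFrame, list[FoldResult]]:
    """Fit every model on every fold and collect the tidy metric matrix.

    ``models`` maps name -> factory; a factory is called with no arguments
    and must return an object with ``fit(X_train, y_train)`` and
    ``decision_function(X_test)``; an optional ``selected_features``
    attribute (list of column names) records feature-selection output.
    Returns a DataFrame with one row per (model, fold).
    """
    y = np.asarray(y)
    n = len(y)
    all_idx = np.arange(n)
    rows = []
    for name, factory in models.items():
        for fold_i, test_idx in enumerate(folds, start=1):
            train_idx = np.setdiff1d(all_idx, test_idx)
            model = factory()
            model.fit(X.iloc[train_idx], y[train_idx])
            scores = np.asarray(model.decision_function(X.iloc[test_idx]), float)
            selected = getattr(model, "selected_features", None)
            n_feat = len(selected) if selected is not None else X.shape[1]
            p, r, f = prf(scores, y[test_idx], threshold)
            fpr, tpr, _ = roc_curve(y[test_idx], scores)
            rows.append(
                FoldResult(
                    model=name, fold=fold_i,
                    auroc=auroc(scores, y[test_idx]),
                    precision=p, recall=r, f_measure=f,
                    n_features=n_feat, roc_points=(fpr, tpr),
                )
            )
    return pd.DataFrame(
        [
            {
                "model": r.model, "fold": r.fold, "auroc": r.auroc,
                "precision": r.precision, "recall": r.recall,
                "f_measure": r.f_measure, "n_features": r.n_features,
            }
            for r in rows
        ]
    ), rows
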