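"""Nested cross-validation and recall-oriented evaluation.

The evaluation protocol mirrors a screening setting: 7 stratified outer folds
give the unbiased performance estimate, and 5 inner folds on each outer
training split select the regularization constant C.  Minority-class
upsampling, when enabled, is applied to *training* splits only — inner as
well as outer — so no artificial row is ever scored.

The headline metric is the F2 score,

    F2 = 5 * precision * recall / (4 * precision + recall),

which weighs recall four times as heavily as precision: missing a child who
needs a full evaluation is far costlier than a false alarm.  Pooled metrics
sum the confusion counts over outer folds; per-fold metrics are also kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.model_selection import StratifiedKFold

from .imbalance import InterpolationUpsampler
from .svm import SquaredHingeSVM
from .text import FeatureMatrix

__all__ = [
    "f2_score",
    "compute_metrics",
    "EvalReport",
    "nested_cv",
    "DEFAULT_C_GRID",
]

#: C grid searched by the inner folds: powers of two spanning weak to strong
#: loss weighting.
DEFAULT_C_GRID = tuple(2.0 ** p for p in range(-5, 6, 2))


def f2_score(precision: float, recall: float) -> float:
    """F-beta with beta=2: 5PR / (4P + R); 0 when the denominator is 0."""
    denom = 4.0 * precision + recall
    if denom == 0:
        return 0.0
    return 5.0 * precision * recall / denom


def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int]) -> dict:
    """Confusion counts plus accuracy, precision, recall and F2."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": (tp + tn) / yt.size,
        "precision": precision,
        "recall": recall,
        "f2": f2_score(precision, recall),
    }


@dataclass
class EvalReport:
    """Per-fold and pooled nested-CV results."""

    per_fold: list[dict]
    pooled: dict
    fold_assignments: dict[int, int]
    chosen_C: list[float]
    models: list[SquaredHingeSVM] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "pooled": self.pooled,
            "fold_assignments": {str(k): v for k, v in
                                 self.fold_assignments.items()},
            "chosen_C": self.chosen_C,
        }


def _slice_rows(X, idx):
    if sp.issparse(X):
        return X.tocsr()[idx]
    return np.asarray(X)[idx]


def _fit_eval(X_tr, y_tr, X_te, y_te, penalty, C, upsampler, seed):
    if upsampler is not None:
        up = InterpolationUpsampler(upsampler["n_per_positive"],
                                    upsampler.get("k"), seed=seed)
        X_tr, y_tr, _ = up.fit_resample(X_tr, y_tr)
    clf = SquaredHingeSVM(penalty=penalty, C=C).fit(X_tr, y_tr)
    return clf, compute_metrics(y_te, clf.predict(X_te))


def nested_cv(features: FeatureMatrix | np.ndarray | None,
              labels: Sequence[int],
              outer_k: int = 7,
              inner_k: int = 5,
              C_grid: Sequence[float] = DEFAULT_C_GRID,
              penalty: str | None = None,
              upsample_cfg: dict | None = None,
              seed: int = 0,
              featurizer: Callable[[np.ndarray, np.ndarray],
                                   tuple[np.ndarray, np.ndarray]] | None = None,
              ) -> EvalReport:
    """Stratified nested cross-validation of a squared-hinge linear SVM.

    Parameters
    ----------
    features : FeatureMatrix, array, or None
        Precomputed document features.  Pass ``None`` with ``featurizer``
        when features must be fitted per fold (e.g. paragraph vectors, whose
        training may only see the outer training split).
    labels : 0/1 per document.
    penalty : "l1", "l2" or None
        ``None`` takes the FeatureMatrix's penalty hint.
    upsample_cfg : dict or None
        E.g. ``{"n_per_positive": 2, "k": 2}``; applied to training splits
        only (outer and inner).
    featurizer : callable
        ``featurizer(train_idx, test_idx) -> (X_train, X_test)``; must fit
        any trainable representation on the training rows only.

    Raises
    ------
    ValueError
        If any fold misses a class (the error names the fold).
    """
    y = np.asarray(labels, dtype=int)
    n = y.shape[0]
    if n < outer_k:
        raise ValueError("fewer documents than outer folds")
    if features is None and featurizer is None:
        raise ValueError("provide features or a featurizer")

    if isinstance(features, FeatureMatrix):
        X_all = features.values
        if penalty is None:
            penalty = features.penalty_hint
    else:
        X_all = features
    if penalty is None:
        penalty = "l2"

    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < outer_k:
        raise ValueError(
            f"every outer fold needs both classes: class "
            f"{int(np.argmin(class_counts))} has {int(class_counts.min())} "
            f"member(s) for {outer_k} folds")

    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    per_fold, chosen_C, models = [], [], []
    fold_assignments: dict[int, int] = {}
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    seen = np.zeros(n, dtype=int)

    for fold, (tr_idx, te_idx) in enumerate(outer.split(np.zeros(n), y)):
        for name, idx in (("train", tr_idx), ("test", te_idx)):
            if np.unique(y[idx]).size < 2:
                raise ValueError(f"outer fold {fold} {name} split misses a class")
        if featurizer is not None:
            X_tr, X_te = featurizer(tr_idx, te_idx)
        else:
            X_tr, X_te = _slice_rows(X_all, tr_idx), _slice_rows(X_all, te_idx)
        y_tr, y_te = y[tr_idx], y[te_idx]

        # inner loop: mean F2 over inner folds per C; ties -> smaller C
        if np.bincount(y_tr, minlength=2).min() < inner_k:
            raise ValueError(f"inner folds of outer fold {fold} would miss "
                             "a class")
        best_C, best_f2 = None, -1.0
        inner = StratifiedKFold(n_splits=inner_k, shuffle=True,
                                random_state=seed + 1)
        inner_splits = list(inner.split(np.zeros(len(y_tr)), y_tr))
        for C in sorted(C_grid):
            scores = []
            for j, (itr, ival) in enumerate(inner_splits):
                if np.unique(y_tr[itr]).size < 2:
                    raise ValueError(f"inner fold {j} of outer fold {fold} "
                                     "misses a class")
                _, m = _fit_eval(_slice_rows(X_tr, itr), y_tr[itr],
                                 _slice_rows(X_tr, ival), y_tr[ival],
                                 penalty, C, upsample_cfg,
                                 seed + 100 * fold + j)
                scores.append(m["f2"])
            mean_f2 = float(np.mean(scores))
            if mean_f2 > best_f2:
                best_C, best_f2 = C, mean_f2

        clf, metrics = _fit_eval(X_tr, y_tr, X_te, y_te, penalty, best_C,
                                 upsample_cfg, seed + 100 * fold + 99)
        metrics["fold"] = fold
        metrics["C"] = best_C
        per_fold.append(metrics)
        chosen_C.append(best_C)
        models.append(clf)
        pooled_true.append(y_te)
        pooled_pred.append(clf.predict(X_te))
        for i in te_idx:
            fold_assignments[int(i)] = fold
            seen[i] += 1

    if not (seen == 1).all():
        raise AssertionError("each document must be tested exactly once")
    pooled = compute_metrics(np.concatenate(pooled_true),
                             np.concatenate(pooled_pred))
    return EvalReport(per_fold=per_fold, pooled=pooled,
                      fold_assignments=fold_assignments,
                      chosen_C=chosen_C, models=models)
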