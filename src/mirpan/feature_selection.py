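"""Two-stage feature selection.

Stage 1 is a correlation screen: each feature is scored by the largest
absolute Pearson (point-biserial) correlation with any one-vs-rest class
indicator, and features below a relevance threshold are dropped.  Stage 2
is recursive feature elimination (RFE): a linear-kernel one-vs-rest
maximum-margin classifier is refit each round, features are ranked by the
sum of squared weights across classes, and the lowest-ranked fraction is
removed until exactly the budget remains.  Both stages are meant to run
inside each training fold of a cross-validation; the cross-fold
intersection of selections is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import cross_val_score
from sklearn.svm import LinearSVC

from .datasets import ExpressionDataset

__all__ = [
    "FeatureSelectionResult",
    "correlation_screen",
    "recursive_feature_elimination",
    "cross_fold_common_features",
    "select_features",
]


@dataclass
class FeatureSelectionResult:
    stage1_features: list[str] = field(default_factory=list)
    stage2_features: list[str] = field(default_factory=list)
    per_fold_selections: dict[int, list[str]] = field(default_factory=dict)
    common_features: list[str] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)
    rfe_cv_accuracy_per_round: list[float] = field(default_factory=list)
    constant_features: list[str] = field(default_factory=list)


def _as_matrix(data, labels):
    if isinstance(data, ExpressionDataset):
        X = data.values
        y = data.labels if labels is None else labels
    else:
        X = pd.DataFrame(data)
        y = labels
    if y is None:
        raise ValueError("labels are required")
    return X, pd.Series(np.asarray(y), index=X.index)


def correlation_screen(
    data: ExpressionDataset | pd.DataFrame,
    labels=None,
    threshold: float = 0.1,
) -> FeatureSelectionResult:
    """Score = max over classes of |corr(feature, one-vs-rest indicator)|.

    Retains features scoring at or above ``threshold``, ranked descending.
    Constant features score 0 by convention and are logged.
    """
    X, y = _as_matrix(data, labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("correlation screen needs at least two classes")
    M = X.to_numpy(dtype=float)
    n = M.shape[0]
    Xc = M - M.mean(axis=0)
    sx = M.std(axis=0, ddof=0)
    constant = sx == 0
    scores = np.zeros(M.shape[1])
    for cls in classes:
        ind = (y.to_numpy() == cls).astype(float)
        ic = ind - ind.mean()
        s_ind = ind.std(ddof=0)
        if s_ind == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (Xc.T @ ic) / (n * sx * s_ind)
        corr[constant] = 0.0
        scores = np.maximum(scores, np.abs(corr))
    score_map = dict(zip(X.columns, scores))
    order = np.argsort(-scores, kind="stable")
    kept = [X.columns[j] for j in order if scores[j] >= threshold]
    return FeatureSelectionResult(
        stage1_features=kept,
        scores={k: float(v) for k, v in score_map.items()},
        constant_features=[c for c, is_const in zip(X.columns, constant) if is_const],
    )


def recursive_feature_elimination(
    data: ExpressionDataset | pd.DataFrame,
    labels=None,
    budget: int = 60,
    step_fraction: float = 0.1,
    record_cv: bool = False,
    cv: int = 3,
    seed: int = 0,
) -> FeatureSelectionResult:
    """Backwards elimination with a linear one-vs-rest margin ranking.

    Each round fits LinearSVC (one-vs-rest), ranks features by the summed
    squared weight across classes, and removes the lowest-ranked
    ``step_fraction`` of the surviving features (at least one) until exactly
    ``budget`` remain.  With ``record_cv`` the internal cross-validated
    accuracy of each round's model is logged.
    """
    X, y = _as_matrix(data, labels)
    if budget > X.shape[1]:
        raise ValueError(f"budget {budget} exceeds available features {X.shape[1]}")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    surviving = list(X.columns)
    cv_log: list[float] = []
    yarr = y.to_numpy()
    while len(surviving) > budget:
        M = X[surviving].to_numpy(dtype=float)
        model = LinearSVC(dual=False, C=1.0, max_iter=5000, random_state=seed)
        model.fit(M, yarr)
        if record_cv:
            cv_log.append(float(np.mean(cross_val_score(model, M, yarr, cv=cv))))
        w = model.coef_
        importance = (w**2).sum(axis=0) if w.ndim == 2 else w**2
        n_drop = max(1, int(np.floor(step_fraction * len(surviving))))
        n_drop = min(n_drop, len(surviving) - budget)
        drop_idx = np.argsort(importance, kind="stable")[:n_drop]
        dropped = {surviving[j] for j in drop_idx}
        surviving = [f for f in surviving if f not in dropped]
    return FeatureSelectionResult(
        stage1_features=list(X.columns),
        stage2_features=surviving,
        rfe_cv_accuracy_per_round=cv_log,
    )


def cross_fold_common_features(per_fold_selections: dict[int, list[str]]) -> list[str]:
    """Intersection of per-fold selections, ordered by mean within-fold rank."""
    if not per_fold_selections:
        raise ValueError("need at least one fold")
    folds = list(per_fold_selections.values())
    common = set(folds[0]).intersection(*folds[1:])
    mean_rank = {
        f: float(np.mean([fold.index(f) for fold in folds])) for f in common
    }
    return sorted(common, key=lambda f: (mean_rank[f], f))


def select_features(
    data: ExpressionDataset | pd.DataFrame,
    labels=None,
    threshold: float = 0.1,
    budget: int = 60,
    step_fraction: float = 0.1,
    seed: int = 0,
) -> FeatureSelectionResult:
    """Run both stages on one training set: screen, then RFE to budget."""
    stage1 = correlation_screen(data, labels, threshold=threshold)
    X, y = _as_matrix(data, labels)
    kept = stage1.stage1_features
    if not kept:
        raise ValueError(f"correlation screen at threshold {threshold} kept no features")
    effective_budget = min(budget, len(kept))
    stage2 = recursive_feature_elimination(
        X[kept], y, budget=effective_budget, step_fraction=step_fraction, seed=seed
    )
    return FeatureSelectionResult(
        stage1_features=kept,
        stage2_features=stage2.stage2_features,
        scores=stage1.scores,
        constant_features=stage1.constant_features,
        rfe_cv_accuracy_per_round=stage2.rfe_cv_accuracy_per_round,
    )
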