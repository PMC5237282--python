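"""Multi-class cancer-type classification and its evaluation metrics.

The evaluation protocol is stratified k-fold cross-validation repeated
several times; per fold, standardization statistics and (optionally) the
two-stage feature selection are fit on the training portion only and
applied to the held-out portion.  Predictions from every repeat are
aggregated into a single confusion matrix whose rows are predictions and
columns are truth.  Overall accuracy is trace/total; agreement beyond
chance is summarized by Cohen's kappa; per-class sensitivity and
specificity are one-vs-rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datasets import ClassifierSpec, ExpressionDataset
from .feature_selection import select_features
from .preprocess import standardize

__all__ = [
    "EvaluationReport",
    "build_classifier",
    "median_heuristic_gamma",
    "repeated_stratified_cv",
    "compute_kappa",
    "per_class_metrics",
    "pool_normals",
    "confusion_from_predictions",
]


@dataclass
class EvaluationReport:
    """Aggregated cross-validation outcome."""

    confusion: pd.DataFrame  # rows = predicted, columns = true
    overall_accuracy: float
    kappa: float
    per_class_sensitivity: dict[str, float]
    per_class_specificity: dict[str, float]
    per_run_accuracies: list[float] = field(default_factory=list)
    per_fold_selections: dict[int, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
            "per_class_sensitivity": self.per_class_sensitivity,
            "per_class_specificity": self.per_class_specificity,
            "per_run_accuracies": self.per_run_accuracies,
            "confusion": {
                "classes": list(self.confusion.columns),
                "counts": self.confusion.to_numpy().tolist(),
            },
        }


class LogisticModelTree(ClassifierMixin, BaseEstimator):
    """Shallow decision tree with a multinomial logistic model in each leaf.

    Leaves whose samples are single-class (or too few to fit) fall back to
    the leaf's empirical class distribution.
    """

    def __init__(self, max_depth: int = 2, C: float = 1.0, random_state: int = 0):
        self.max_depth = max_depth
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.tree_ = DecisionTreeClassifier(
            max_depth=self.max_depth, random_state=self.random_state
        ).fit(X, y)
        self.leaf_models_ = {}
        leaves = self.tree_.apply(X)
        for leaf in np.unique(leaves):
            idx = leaves == leaf
            y_leaf = y[idx]
            if np.unique(y_leaf).size >= 2 and idx.sum() >= 5:
                model = LogisticRegression(C=self.C, max_iter=1000).fit(X[idx], y_leaf)
                self.leaf_models_[leaf] = ("logistic", model)
            else:
                prior = np.array([(y_leaf == c).mean() for c in self.classes_])
                self.leaf_models_[leaf] = ("prior", prior)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        leaves = self.tree_.apply(X)
        out = np.zeros((X.shape[0], self.classes_.size))
        for leaf in np.unique(leaves):
            idx = leaves == leaf
            kind, model = self.leaf_models_[leaf]
            if kind == "logistic":
                proba = model.predict_proba(X[idx])
                cols = np.searchsorted(self.classes_, model.classes_)
                out[np.ix_(idx, cols)] = proba
            else:
                out[idx] = model
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width 1/(2*sigma^2) with sigma = median pairwise distance."""
    n = X.shape[0]
    if n > 200:
        rng = np.random.default_rng(0)
        X = X[rng.choice(n, 200, replace=False)]
    d = pairwise_distances(X)
    med = np.median(d[np.triu_indices_from(d, k=1)])
    if med <= 0:
        return 1.0 / X.shape[1]
    return 1.0 / (2.0 * med**2)


def build_classifier(spec: ClassifierSpec, X: np.ndarray | None = None, seed: int = 0):
    """Instantiate the sklearn estimator for a classifier family."""
    hp = dict(spec.hyperparameters)

    def _calibrated(svc):
        # sigmoid (Platt) calibration fit on internal training folds
        if not spec.probability_calibration:
            return svc
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)

    if spec.family == "svm_linear":
        return _calibrated(SVC(kernel="linear", C=hp.get("cost", 1.0), random_state=seed))
    if spec.family == "svm_radial":
        gamma = hp.get("sigma")
        if gamma is None:
            gamma = median_heuristic_gamma(X) if X is not None else "scale"
        return _calibrated(
            SVC(kernel="rbf", C=hp.get("cost", 1.0), gamma=gamma, random_state=seed)
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 200), random_state=seed
        )
    if spec.family == "lda":
        return LinearDiscriminantAnalysis()
    if spec.family == "naive_bayes":
        return GaussianNB()
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=hp.get("k", 5))
    if spec.family == "logistic_tree":
        return LogisticModelTree(
            max_depth=hp.get("max_depth", 2), C=hp.get("C", 1.0), random_state=seed
        )
    raise ValueError(f"unknown family {spec.family}")


def confusion_from_predictions(y_true, y_pred, classes=None) -> pd.DataFrame:
    """Count matrix with rows = predicted label, columns = true label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[index[p], index[t]] += 1
    return pd.DataFrame(mat, index=classes, columns=classes)


def compute_kappa(confusion: pd.DataFrame | np.ndarray) -> float:
    """Cohen's kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (trace/total); p_e the chance agreement
    from the marginals.  A degenerate matrix with p_e = 1 returns 0.
    """
    mat = np.asarray(confusion, dtype=float)
    total = mat.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(mat) / total
    p_e = float((mat.sum(axis=1) * mat.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def per_class_metrics(
    confusion: pd.DataFrame,
) -> tuple[dict[str, float], dict[str, float]]:
    """One-vs-rest sensitivity and specificity per class.

    A class absent from the truth column margin has undefined sensitivity
    (NaN), not zero.
    """
    mat = confusion.to_numpy(dtype=float)
    total = mat.sum()
    sens, spec = {}, {}
    for i, cls in enumerate(confusion.columns):
        tp = mat[i, i]
        fn = mat[:, i].sum() - tp  # truth = cls, predicted otherwise
        fp = mat[i, :].sum() - tp
        tn = total - tp - fn - fp
        sens[cls] = float(tp / (tp + fn)) if (tp + fn) > 0 else float("nan")
        spec[cls] = float(tn / (tn + fp)) if (tn + fp) > 0 else float("nan")
    return sens, spec


def pool_normals(labels: pd.Series, normal_flags: pd.Series | None = None) -> pd.Series:
    """Collapse all normal-tissue samples into a single "Normal" class.

    Normals are identified by ``normal_flags`` when given, else by labels
    containing "normal" (case-insensitive).  Cancer labels are untouched.
    """
    labels = labels.copy()
    if normal_flags is not None:
        is_normal = normal_flags.reindex(labels.index).fillna(False).astype(bool)
    else:
        is_normal = labels.astype(str).str.contains("normal", case=False)
    labels[is_normal] = "Normal"
    return labels


def _report_from_confusion(confusion, per_run, per_fold_selections=None) -> EvaluationReport:
    sens, spec = per_class_metrics(confusion)
    total = confusion.to_numpy().sum()
    return EvaluationReport(
        confusion=confusion,
        overall_accuracy=float(np.trace(confusion.to_numpy()) / total),
        kappa=compute_kappa(confusion),
        per_class_sensitivity=sens,
        per_class_specificity=spec,
        per_run_accuracies=per_run,
        per_fold_selections=per_fold_selections or {},
    )


def repeated_stratified_cv(
    data: ExpressionDataset,
    labels: pd.Series | None = None,
    spec: ClassifierSpec = ClassifierSpec(),
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    select: dict | None = None,
    standardize_folds: bool = True,
) -> EvaluationReport:
    """Repeated stratified cross-validation with in-fold fitting.

    Per fold, standardization statistics (and, when ``select`` is given,
    the two-stage feature selection with those keyword arguments) are fit
    on the training portion only.  Returns the aggregated report; the
    per-fold stage-2 selections are recorded for cross-fold intersection.
    """
    y = data.labels if labels is None else labels.reindex(data.values.index)
    if y is None:
        raise ValueError("labels are required")
    counts = y.value_counts()
    too_small = counts[counts < folds]
    if len(too_small):
        raise ValueError(
            f"classes smaller than fold count {folds}: {dict(too_small)}"
        )
    classes = sorted(y.unique())
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    per_run: list[float] = []
    selections: dict[int, list[str]] = {}
    yarr = y.to_numpy()
    for fold_id, (train, test) in enumerate(splitter.split(data.values, yarr)):
        X_train = data.values.iloc[train]
        X_test = data.values.iloc[test]
        y_train, y_test = yarr[train], yarr[test]
        if standardize_folds:
            train_ds, stats = standardize(ExpressionDataset(values=X_train))
            test_ds, _ = standardize(ExpressionDataset(values=X_test), stats)
            X_train, X_test = train_ds.values, test_ds.values
        if select is not None:
            sel = select_features(X_train, pd.Series(y_train, index=X_train.index), **select)
            selections[fold_id] = sel.stage2_features
            X_train = X_train[sel.stage2_features]
            X_test = X_test[sel.stage2_features]
        model = build_classifier(spec, X_train.to_numpy(), seed=seed)
        model.fit(X_train.to_numpy(), y_train)
        y_pred = model.predict(X_test.to_numpy())
        confusion += confusion_from_predictions(y_test, y_pred, classes=classes)
        per_run.append(float(np.mean(y_pred == y_test)))
    return _report_from_confusion(confusion, per_run, selections)
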