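"""Treatment-outcome modelling and recommendation.

The prognosis model predicts remission vs recurrence (assessed at >= 300
days of follow-up) from a fixed-order feature vector: a block of selected
miRNA features (z-scored with training statistics), clinical covariates
(z-scored age, one-hot gender and ethnicity), a one-hot cancer-type block,
and the 3 Cox-scaled coordinates of the patient's (merged) treatment.

Cohort eligibility is the paper-style triple rule applied to a fixed point:
complete clinical information with >= 300 days follow-up, then at least
five records per cancer type and at least five per unique (merged)
treatment, iterated because each drop can invalidate the other rule.

Class imbalance (few recurrences) is corrected on the training partition
only by SMOTE: synthetic minority samples are convex combinations
``x + u * (neighbor - x)`` with ``u ~ Uniform(0,1)`` between a minority
sample and one of its k nearest minority neighbors.

The recommender scores every treatment cluster by swapping its coordinates
into the patient's feature vector and ranking the calibrated remission
probabilities.  A self-training update admits unlabeled samples whose
highest predicted class probability strictly exceeds a threshold (0.95)
and refits on the union; original labels are never overwritten.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import train_test_split

from .datasets import ClassifierSpec, ClinicalRecord, ExpressionDataset
from .diagnosis import EvaluationReport, build_classifier, confusion_from_predictions, _report_from_confusion
from .treatments import TreatmentCatalog

__all__ = [
    "FeatureEncoders",
    "PrognosisModel",
    "RecommendationResult",
    "filter_cohort",
    "fit_encoders",
    "assemble_features",
    "assemble_matrix",
    "smote_balance",
    "train_prognosis",
    "recommend",
    "self_training_update",
]

OUTCOME_CLASSES = ("recurrence", "remission")  # recurrence = "disease" positive class
MIN_GROUP_SIZE = 5
MIN_FOLLOWUP_DAYS = 300


def filter_cohort(
    records: list[ClinicalRecord],
    expression: ExpressionDataset | None = None,
    catalog: TreatmentCatalog | None = None,
    min_group: int = MIN_GROUP_SIZE,
    min_followup: int = MIN_FOLLOWUP_DAYS,
) -> tuple[list[ClinicalRecord], list[dict]]:
    """Apply the three eligibility rules to a fixed point.

    Rule 1: complete clinical information (gender, age, ethnicity, cancer
    type, treatment, outcome) with follow-up >= ``min_followup`` days, and
    an expression sample when ``expression`` is given.  Rules 2 and 3:
    at least ``min_group`` records per cancer type and per unique
    treatment (merged cluster when a catalog is given), iterated until no
    rule fires.  Returns survivors plus an audit log of (patient, reason)
    drops.
    """
    audit: list[dict] = []
    survivors = []
    sample_ids = set(expression.sample_ids) if expression is not None else None
    for rec in records:
        if not rec.is_complete():
            audit.append({"patient_id": rec.patient_id, "reason": "incomplete clinical record"})
        elif rec.followup_days < min_followup:
            audit.append({"patient_id": rec.patient_id, "reason": f"follow-up < {min_followup} days"})
        elif sample_ids is not None and rec.patient_id not in sample_ids:
            audit.append({"patient_id": rec.patient_id, "reason": "no expression sample"})
        else:
            survivors.append(rec)

    def treatment_key(rec: ClinicalRecord):
        if catalog is not None:
            return catalog.cluster_of(rec.treatment_id)
        return rec.treatment_id

    changed = True
    while changed:
        changed = False
        type_counts = pd.Series([r.cancer_type for r in survivors]).value_counts()
        small_types = set(type_counts.index[type_counts < min_group])
        if small_types:
            keep, dropped = [], []
            for r in survivors:
                (keep if r.cancer_type not in small_types else dropped).append(r)
            for r in dropped:
                audit.append({"patient_id": r.patient_id, "reason": f"cancer type {r.cancer_type} has < {min_group} records"})
            survivors = keep
            changed = changed or bool(dropped)
        treat_counts = pd.Series([treatment_key(r) for r in survivors]).value_counts()
        small_treats = set(treat_counts.index[treat_counts < min_group])
        if small_treats:
            keep, dropped = [], []
            for r in survivors:
                (keep if treatment_key(r) not in small_treats else dropped).append(r)
            for r in dropped:
                audit.append({"patient_id": r.patient_id, "reason": f"treatment {treatment_key(r)} has < {min_group} records"})
            survivors = keep
            changed = changed or bool(dropped)
    if not survivors:
        raise ValueError("no records survive cohort eligibility filtering")
    return survivors, audit


@dataclass
class FeatureEncoders:
    """Training-partition statistics and category levels for assembly."""

    mirna_features: list[str]
    mirna_mean: pd.Series
    mirna_sd: pd.Series
    age_mean: float
    age_sd: float
    gender_levels: list[str]
    ethnicity_levels: list[str]
    cancer_type_levels: list[str]
    # treatment-coordinate block statistics (over training patients), so the
    # block lives on the same z-scale as every other numeric feature
    coord_mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    coord_sd: np.ndarray = field(default_factory=lambda: np.ones(3))

    def column_names(self, include_mirna: bool = True) -> list[str]:
        cols = []
        if include_mirna:
            cols += [f"mirna:{f}" for f in self.mirna_features]
        cols += ["clinical:age"]
        cols += [f"gender:{g}" for g in self.gender_levels]
        cols += [f"ethnicity:{e}" for e in self.ethnicity_levels]
        cols += [f"cancer_type:{c}" for c in self.cancer_type_levels]
        cols += ["treatment:x", "treatment:y", "treatment:z"]
        return cols


def fit_encoders(
    records: list[ClinicalRecord],
    expression: ExpressionDataset,
    mirna_features: list[str] | None = None,
    catalog: TreatmentCatalog | None = None,
) -> FeatureEncoders:
    """Fit standardization statistics and category levels on training records."""
    if mirna_features is None:
        mirna_features = expression.feature_ids
    ids = [r.patient_id for r in records]
    block = expression.values.loc[ids, mirna_features]
    sd = block.std(axis=0, ddof=0).replace(0.0, 1.0)
    ages = np.array([r.age for r in records], dtype=float)
    age_sd = float(ages.std()) or 1.0
    coord_mean, coord_sd = np.zeros(3), np.ones(3)
    if catalog is not None:
        coords = np.array([catalog.coordinates_of(r.treatment_id) for r in records])
        coord_mean = coords.mean(axis=0)
        coord_sd = coords.std(axis=0)
        coord_sd[coord_sd == 0] = 1.0
    return FeatureEncoders(
        mirna_features=list(mirna_features),
        mirna_mean=block.mean(axis=0),
        mirna_sd=sd,
        age_mean=float(ages.mean()),
        age_sd=age_sd,
        gender_levels=sorted({r.gender for r in records}),
        ethnicity_levels=sorted({r.ethnicity for r in records}),
        cancer_type_levels=sorted({r.cancer_type for r in records}),
        coord_mean=coord_mean,
        coord_sd=coord_sd,
    )


def _one_hot(value: str | None, levels: list[str]) -> np.ndarray:
    vec = np.zeros(len(levels))
    if value in levels:
        vec[levels.index(value)] = 1.0
    return vec  # unseen category -> all-zero block


def assemble_features(
    record: ClinicalRecord,
    expression: ExpressionDataset,
    catalog: TreatmentCatalog,
    encoders: FeatureEncoders,
    include_mirna: bool = True,
    treatment_coords: np.ndarray | None = None,
) -> np.ndarray:
    """Build one patient's feature vector in the documented column order.

    ``treatment_coords`` overrides the record's own treatment (used by the
    recommender to scan the catalog).
    """
    parts = []
    if include_mirna:
        row = expression.values.loc[record.patient_id, encoders.mirna_features]
        parts.append(((row - encoders.mirna_mean) / encoders.mirna_sd).to_numpy(dtype=float))
    parts.append(np.array([(record.age - encoders.age_mean) / encoders.age_sd]))
    parts.append(_one_hot(record.gender, encoders.gender_levels))
    parts.append(_one_hot(record.ethnicity, encoders.ethnicity_levels))
    parts.append(_one_hot(record.cancer_type, encoders.cancer_type_levels))
    if treatment_coords is None:
        treatment_coords = catalog.coordinates_of(record.treatment_id)
    coords = np.asarray(treatment_coords, dtype=float)
    if coords.shape != (3,):
        raise ValueError("treatment coordinate block must have length 3")
    parts.append((coords - encoders.coord_mean) / encoders.coord_sd)
    return np.concatenate(parts)


def assemble_matrix(
    records: list[ClinicalRecord],
    expression: ExpressionDataset,
    catalog: TreatmentCatalog,
    encoders: FeatureEncoders,
    include_mirna: bool = True,
) -> pd.DataFrame:
    rows = [
        assemble_features(r, expression, catalog, encoders, include_mirna=include_mirna)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        index=[r.patient_id for r in records],
        columns=encoders.column_names(include_mirna=include_mirna),
    )


def smote_balance(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Raise the minority class to the majority count by interpolation.

    Each synthetic sample is ``x + u * (neighbor - x)`` for a random
    minority sample x, one of its k nearest minority neighbors, and
    ``u ~ Uniform(0, 1)``.  Balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE balancing expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X, y
    minority_X = X[y == minority]
    if minority_X.shape[0] < 2:
        raise ValueError("minority class needs >= 2 members to interpolate")
    k_eff = min(k, minority_X.shape[0] - 1)
    # nearest minority neighbors, excluding self
    d = np.linalg.norm(minority_X[:, None, :] - minority_X[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    neighbor_idx = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
    rng = np.random.default_rng(seed)
    synthetic = np.empty((n_needed, X.shape[1]))
    for s in range(n_needed):
        i = int(rng.integers(minority_X.shape[0]))
        j = int(neighbor_idx[i, rng.integers(k_eff)])
        u = rng.random()
        synthetic[s] = minority_X[i] + u * (minority_X[j] - minority_X[i])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


@dataclass
class PrognosisModel:
    """Fitted outcome model plus everything needed to score new patients."""

    classifier: object
    encoders: FeatureEncoders
    catalog: TreatmentCatalog
    include_mirna: bool
    expression: ExpressionDataset  # training-cohort expression (for refits)
    train_X: np.ndarray
    train_y: np.ndarray
    report: EvaluationReport | None = None

    def predict_remission_probability(self, X: np.ndarray) -> np.ndarray:
        proba = self.classifier.predict_proba(np.atleast_2d(X))
        col = list(self.classifier.classes_).index("remission")
        return proba[:, col]


@dataclass
class RecommendationResult:
    """Treatment clusters ranked by predicted remission probability."""

    ranking: list[tuple[int, float]]  # (cluster id, probability), non-increasing

    @property
    def best_cluster(self) -> int:
        return self.ranking[0][0]

    def to_json(self) -> dict:
        return {"ranking": [{"cluster": int(c), "remission_probability": float(p)} for c, p in self.ranking]}


def train_prognosis(
    records: list[ClinicalRecord],
    expression: ExpressionDataset,
    catalog: TreatmentCatalog,
    mirna_features: list[str] | None = None,
    split: float = 0.75,
    spec: ClassifierSpec | None = None,
    smote_k: int = 5,
    seed: int = 0,
) -> tuple[PrognosisModel, PrognosisModel]:
    """Fit the outcome model with and without the miRNA block.

    The cohort is split 75-25 stratified on outcome; encoders and SMOTE
    operate on the training partition only, and both models are evaluated
    on the untouched test partition.  Returns (with_mirna, without_mirna)
    models, each carrying its held-out EvaluationReport.
    """
    if spec is None:
        spec = ClassifierSpec(family="svm_radial", probability_calibration=True)
    if not spec.probability_calibration:
        raise ValueError("prognosis classifier must be probability-calibrated")
    y = np.array([r.outcome for r in records])
    if set(np.unique(y)) != set(OUTCOME_CLASSES):
        raise ValueError(f"cohort must contain both outcomes {OUTCOME_CLASSES}")
    idx = np.arange(len(records))
    train_idx, test_idx = train_test_split(
        idx, train_size=split, stratify=y, random_state=seed
    )
    train_records = [records[i] for i in train_idx]
    test_records = [records[i] for i in test_idx]
    encoders = fit_encoders(train_records, expression, mirna_features, catalog=catalog)

    models = []
    for include_mirna in (True, False):
        X_train = assemble_matrix(train_records, expression, catalog, encoders, include_mirna).to_numpy()
        X_test = assemble_matrix(test_records, expression, catalog, encoders, include_mirna).to_numpy()
        y_train, y_test = y[train_idx], y[test_idx]
        X_bal, y_bal = smote_balance(X_train, y_train, k=smote_k, seed=seed)
        clf = build_classifier(spec, X_bal, seed=seed)
        clf.fit(X_bal, y_bal)
        y_pred = clf.predict(X_test)
        confusion = confusion_from_predictions(y_test, y_pred, classes=list(OUTCOME_CLASSES))
        report = _report_from_confusion(confusion, [float(np.mean(y_pred == y_test))])
        models.append(
            PrognosisModel(
                classifier=clf,
                encoders=encoders,
                catalog=catalog,
                include_mirna=include_mirna,
                expression=expression,
                train_X=X_bal,
                train_y=y_bal,
                report=report,
            )
        )
    return models[0], models[1]


def recommend(
    record: ClinicalRecord,
    model: PrognosisModel,
    catalog: TreatmentCatalog | None = None,
    expression: ExpressionDataset | None = None,
    top_k: int = 3,
) -> RecommendationResult:
    """Rank treatment clusters by predicted remission probability.

    The patient's feature vector is rebuilt once per cluster with that
    cluster's coordinates in the treatment block; ties in probability are
    broken by ascending cluster id, so the result is independent of the
    catalog's enumeration order.
    """
    catalog = catalog or model.catalog
    expression = expression or model.expression
    clusters = catalog.cluster_ids
    if not clusters:
        raise ValueError("treatment catalog is empty")
    rows = np.vstack(
        [
            assemble_features(
                record, expression, catalog, model.encoders,
                include_mirna=model.include_mirna,
                treatment_coords=catalog.coordinates[c],
            )
            for c in clusters
        ]
    )
    probs = model.predict_remission_probability(rows)
    order = sorted(range(len(clusters)), key=lambda i: (-probs[i], clusters[i]))
    ranking = [(clusters[i], float(probs[i])) for i in order]
    return RecommendationResult(ranking=ranking[: max(1, top_k)])


def self_training_update(
    model: PrognosisModel,
    X_unlabeled: np.ndarray,
    threshold: float = 0.95,
) -> tuple[PrognosisModel, list[dict]]:
    """Admit confidently pseudo-labeled samples and refit.

    A candidate is admitted only when its maximum predicted class
    probability strictly exceeds ``threshold`` (a candidate at exactly the
    threshold is rejected).  The refit model trains on the union of the
    original training data and the admitted pseudo-labeled samples; the
    original labels are never altered.  Zero admissions is a valid no-op
    returning the model unchanged.
    """
    X_unlabeled = np.atleast_2d(np.asarray(X_unlabeled, dtype=float))
    proba = model.classifier.predict_proba(X_unlabeled)
    max_prob = proba.max(axis=1)
    pseudo = model.classifier.classes_[np.argmax(proba, axis=1)]
    admitted = np.flatnonzero(max_prob > threshold)
    audit = [
        {
            "index": int(i),
            "pseudo_label": str(pseudo[i]),
            "probability": float(max_prob[i]),
            "admitted": bool(max_prob[i] > threshold),
        }
        for i in range(X_unlabeled.shape[0])
    ]
    if admitted.size == 0:
        return model, audit
    X_new = np.vstack([model.train_X, X_unlabeled[admitted]])
    y_new = np.concatenate([model.train_y, pseudo[admitted]])
    refit = clone(model.classifier)
    refit.fit(X_new, y_new)
    updated = PrognosisModel(
        classifier=refit,
        encoders=model.encoders,
        catalog=model.catalog,
        include_mirna=model.include_mirna,
        expression=model.expression,
        train_X=X_new,
        train_y=y_new,
        report=model.report,
    )
    return updated, audit
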