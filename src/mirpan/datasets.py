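"""Core in-memory containers shared by every pipeline stage.

Expression data is held as a pandas DataFrame (rows = samples, columns =
miRNA features) with ``NaN`` marking missing entries; the boolean observed
mask is derived, never stored separately, so the two can never disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ClinicalRecord",
    "OutcomeCoefficients",
    "SimulationConfig",
    "PreprocessConfig",
    "ClassifierSpec",
]


@dataclass
class ExpressionDataset:
    """Samples x miRNA expression matrix with optional class labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Real-valued matrix, index = sample ids, columns = feature ids.
        ``NaN`` encodes a missing measurement.
    labels : pandas.Series, optional
        Per-sample class labels aligned with ``values.index``.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature ids in expression matrix")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.index)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()][:3].tolist()
                raise ValueError(f"labels missing for samples {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def observed_mask(self) -> pd.DataFrame:
        """True where a value was measured."""
        return self.values.notna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of samples with a missing value."""
        return self.values.isna().mean(axis=0)

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        return ExpressionDataset(values=values, labels=self.labels)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionDataset":
        return ExpressionDataset(values=self.values.loc[:, list(feature_ids)], labels=self.labels)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        lab = self.labels.loc[list(sample_ids)] if self.labels is not None else None
        return ExpressionDataset(values=self.values.loc[list(sample_ids)], labels=lab)

    def __eq__(self, other: object) -> bool:  # value equality incl. mask
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        same_values = self.values.equals(other.values)
        if self.labels is None or other.labels is None:
            same_labels = self.labels is None and other.labels is None
        else:
            same_labels = self.labels.equals(other.labels)
        return same_values and same_labels


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's clinical row used for prognosis modelling."""

    patient_id: str
    gender: str | None
    age: float | None
    ethnicity: str | None
    cancer_type: str | None
    treatment_id: str | None
    outcome: str | None  # "remission" | "recurrence"
    followup_days: int | None

    OUTCOMES = ("remission", "recurrence")

    def is_complete(self) -> bool:
        return all(
            v is not None and v == v  # NaN-safe
            for v in (
                self.gender,
                self.age,
                self.ethnicity,
                self.cancer_type,
                self.treatment_id,
                self.outcome,
                self.followup_days,
            )
        )


@dataclass(frozen=True)
class OutcomeCoefficients:
    """Weights in the generative log-odds model for treatment outcome.

    log-odds(remission) = intercept + age*z_age + gender/ethnicity offsets
    + treatment_scale*effect[t] + mirna_main*s + mirna_interaction*s*g[t],
    where s is the patient's planted miRNA signature and g[t] a per-treatment
    susceptibility sign.
    """

    intercept: float = 0.0
    age: float = 0.0
    gender: float = 0.0
    ethnicity: float = 0.0
    treatment_scale: float = 1.0
    mirna_main: float = 0.0
    mirna_interaction: float = 0.0

    @classmethod
    def null(cls) -> "OutcomeCoefficients":
        return cls(treatment_scale=0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study conditions: ~21 tumor classes with
    heterogeneous sample counts, class-specific mean shifts on a subset of
    informative miRNA features, systemic (class-independent) per-feature
    missingness, free-text treatments from a template grammar, and a binary
    remission/recurrence outcome driven by clinical covariates, treatment
    identity and a planted miRNA signature.
    """

    n_classes: int = 21
    samples_per_class: tuple[int, ...] = (
        145, 387, 220, 45, 198, 436, 424, 569, 80, 47, 87,
        312, 461, 156, 56, 91, 326, 526, 187, 474, 80,
    )
    n_features: int = 300
    n_informative: int = 40
    class_effect_size: float = 2.0
    missing_feature_fraction: float = 0.4
    missing_rate_within_feature: float = 0.3
    n_treatments: int = 8
    outcome_coefficients: OutcomeCoefficients = field(
        default_factory=lambda: OutcomeCoefficients(
            intercept=0.3, age=-0.3, gender=0.2, ethnicity=0.2,
            treatment_scale=1.0, mirna_main=0.8, mirna_interaction=0.8,
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes <= 0:
            raise ValueError("n_classes must be positive")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError(
                f"samples_per_class has length {len(self.samples_per_class)}, "
                f"expected n_classes={self.n_classes}"
            )
        if any(n <= 0 for n in self.samples_per_class):
            raise ValueError("samples_per_class entries must be positive")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must not exceed n_features")
        for name in ("missing_feature_fraction", "missing_rate_within_feature"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.class_effect_size < 0:
            raise ValueError("class_effect_size must be nonnegative")
        if self.n_treatments < 1:
            raise ValueError("n_treatments must be positive")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the filter -> impute -> log -> standardize pipeline."""

    missing_threshold: float = 0.2
    knn_k: int = 10
    log_base: float = 2.0  # 2, e, or 10
    log_offset: float = 1.0
    standardize_scope: str = "per_training_fold"  # or "global"

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_threshold <= 1.0:
            raise ValueError("missing_threshold must lie in [0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.log_base not in (2.0, np.e, 10.0):
            raise ValueError("log_base must be one of 2, e, 10")
        if self.log_offset < 0:
            raise ValueError("log_offset must be nonnegative")
        if self.standardize_scope not in ("global", "per_training_fold"):
            raise ValueError("standardize_scope must be 'global' or 'per_training_fold'")


CLASSIFIER_FAMILIES = (
    "svm_linear",
    "svm_radial",
    "random_forest",
    "lda",
    "naive_bayes",
    "knn",
    "logistic_tree",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier family to fit and with what hyperparameters."""

    family: str = "svm_radial"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    probability_calibration: bool = False

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown classifier family {self.family!r}; "
                f"choose one of {CLASSIFIER_FAMILIES}"
            )
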