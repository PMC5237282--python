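"""On-disk formats: expression CSV, clinical CSV, tree JSON, run configs.

Expression CSV dialect: comma-separated UTF-8, header row of miRNA feature
ids, first column the sample id, an empty cell meaning a missing
measurement.  Clinical CSV has one row per patient with fixed column
names.  Both round-trip losslessly, including missingness.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import ClinicalRecord, ExpressionDataset
from .devtree import DevelopmentalTree

__all__ = [
    "read_expression_csv",
    "write_expression_csv",
    "read_clinical_csv",
    "write_clinical_csv",
    "read_tree_json",
    "write_json",
    "RunConfig",
]

CLINICAL_COLUMNS = [
    "patient_id", "gender", "age", "ethnicity",
    "cancer_type", "treatment_id", "outcome", "followup_days",
]


def read_expression_csv(path, labels: pd.Series | None = None) -> ExpressionDataset:
    path = Path(path)
    try:
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except Exception as exc:  # re-raise with the file named
        raise ValueError(f"cannot parse expression CSV {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique()[:3].tolist()
        raise ValueError(f"{path}: duplicated sample ids {dupes}")
    non_numeric = frame.columns[
        [not np.issubdtype(frame[c].dtype, np.number) for c in frame.columns]
    ]
    for col in non_numeric:
        bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: unparseable cell at sample {bad.index[0]!r}, feature {col!r}: {bad.iloc[0]!r}"
            )
        frame[col] = pd.to_numeric(frame[col])
    frame.index = frame.index.astype(str)
    frame.index.name = None
    return ExpressionDataset(values=frame, labels=labels)


def write_expression_csv(data: ExpressionDataset, path) -> None:
    data.values.to_csv(path, index_label="sample_id", na_rep="")


def read_clinical_csv(path) -> list[ClinicalRecord]:
    path = Path(path)
    frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing clinical columns {missing_cols}")
    if frame["patient_id"].duplicated().any():
        dupes = frame.loc[frame["patient_id"].duplicated(), "patient_id"].tolist()[:3]
        raise ValueError(f"{path}: duplicated patient ids {dupes}")

    def clean(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    records = []
    for _, row in frame.iterrows():
        followup = clean(row["followup_days"])
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                gender=clean(row["gender"]),
                age=float(row["age"]) if clean(row["age"]) is not None else None,
                ethnicity=clean(row["ethnicity"]),
                cancer_type=clean(row["cancer_type"]),
                treatment_id=clean(row["treatment_id"]),
                outcome=clean(row["outcome"]),
                followup_days=int(followup) if followup is not None else None,
            )
        )
    return records


def write_clinical_csv(records: list[ClinicalRecord], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "gender": r.gender,
                "age": r.age,
                "ethnicity": r.ethnicity,
                "cancer_type": r.cancer_type,
                "treatment_id": r.treatment_id,
                "outcome": r.outcome,
                "followup_days": r.followup_days,
            }
            for r in records
        ],
        columns=CLINICAL_COLUMNS,
    )
    frame.to_csv(path, index=False, na_rep="")


def read_tree_json(path) -> DevelopmentalTree:
    return DevelopmentalTree.from_file(path)


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


@dataclass
class RunConfig:
    """One serializable document holding every stage's parameters.

    Every stochastic stage draws from a seed recorded here, and artifacts
    embed the config hash so a run can be reproduced exactly.
    """

    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    tree_path: str | None = None
    treatment_merge_threshold: int = 25
    smote_k: int = 5
    split: float = 0.75
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "simulate": dict(self.simulate),
            "preprocess": dict(self.preprocess),
            "selection": dict(self.selection),
            "classifier": dict(self.classifier),
            "tree_path": self.tree_path,
            "treatment_merge_threshold": self.treatment_merge_threshold,
            "smote_k": self.smote_k,
            "split": self.split,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def stamp(self, payload: dict) -> dict:
        """Embed the producing config's hash into an artifact payload."""
        return {**payload, "run_config_hash": self.config_hash()}
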