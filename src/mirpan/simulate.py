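"""Synthetic cohort generator.

Emulates the statistical structure of a pan-cancer miRNA cohort so every
downstream stage (preprocessing, feature selection, diagnosis, tree-climbing,
treatment encoding, prognosis and recommendation) is testable without any
external download:

* ~21 tumor classes with heterogeneous per-class sample counts;
* Gaussian unit-variance features on a log-like scale, with a subset of
  *informative* features whose class means are shifted by a fixed effect
  size under class-specific sign patterns;
* *systemic* missingness — a fraction of features is missing at the same
  rate in every class;
* free-text treatments drawn from a "general treatment, specific method"
  template grammar, including near-duplicates at small edit distance;
* a binary remission/recurrence outcome whose log-odds combine clinical
  covariates, a per-treatment effect, and a planted miRNA signature with a
  signature x treatment interaction.

The generator records its planted truths (informative features, per-patient
best treatment) so recovery can be asserted exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ClinicalRecord, ExpressionDataset, OutcomeCoefficients, SimulationConfig

__all__ = [
    "SyntheticCohort",
    "generate_expression",
    "generate_treatments",
    "generate_outcomes",
    "generate_cohort",
]

GENERAL_TREATMENTS = (
    "chemotherapy", "radiation", "surgery", "immunotherapy", "hormone therapy",
    "targeted therapy", "ancillary", "vaccine", "cryotherapy", "embolization",
)
SPECIFIC_METHODS = (
    "cisplatin", "carboplatin", "paclitaxel", "doxorubicin", "gemcitabine",
    "external beam", "brachytherapy", "resection", "lobectomy", "interferon",
    "tamoxifen", "erlotinib", "bevacizumab", "etoposide", "fluorouracil",
)
GENDERS = ("female", "male")
ETHNICITIES = ("group a", "group b", "group c", "group d")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the planted truths behind it."""

    expression: ExpressionDataset
    clinical: list[ClinicalRecord]
    treatments: dict[str, list[tuple[str, str]]]  # treatment id -> raw items
    true_informative_features: list[str]
    true_best_treatment: dict[str, str]  # patient id -> treatment id
    planted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sample_set = set(self.expression.sample_ids)
        for rec in self.clinical:
            if rec.patient_id not in sample_set:
                raise ValueError(f"clinical record {rec.patient_id} has no expression sample")

    def planted_truths(self) -> dict:
        """JSON-serializable sidecar of planted truths for test assertions."""
        return {
            "true_informative_features": list(self.true_informative_features),
            "true_best_treatment": dict(self.true_best_treatment),
            "treatment_effects": {k: float(v) for k, v in self.planted.get("treatment_effects", {}).items()},
            "treatment_susceptibility": {k: float(v) for k, v in self.planted.get("susceptibility", {}).items()},
        }


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generation stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), stream]))


def generate_expression(config: SimulationConfig, raw_scale: bool = False) -> ExpressionDataset:
    """Draw the samples x features expression matrix.

    Features are standard Gaussian; the first ``n_informative`` features are
    shifted by ``class_effect_size`` with a sign pattern drawn per class.
    ``missing_feature_fraction`` of the features receive missingness at rate
    ``missing_rate_within_feature`` uniformly over samples, independent of
    class (systemic missingness).  With ``raw_scale=True`` the matrix is
    exponentiated (2**x), producing strictly positive count-like values that
    a log2 transform maps back to the simulated scale.
    """
    rng = _rng(config, 1)
    n = int(sum(config.samples_per_class))
    p = config.n_features
    labels = np.repeat([f"C{i:02d}" for i in range(config.n_classes)], config.samples_per_class)

    values = rng.standard_normal((n, p))
    # class-specific +/- effect on the informative block
    signs = rng.choice([-1.0, 1.0], size=(config.n_classes, config.n_informative))
    class_index = np.repeat(np.arange(config.n_classes), config.samples_per_class)
    values[:, : config.n_informative] += config.class_effect_size * signs[class_index]

    n_missing_features = int(round(config.missing_feature_fraction * p))
    missing_features = rng.choice(p, size=n_missing_features, replace=False)
    for j in missing_features:
        holes = rng.random(n) < config.missing_rate_within_feature
        values[holes, j] = np.nan

    if raw_scale:
        values = np.exp2(values)

    sample_ids = [f"P{i:05d}" for i in range(n)]
    feature_ids = [f"hsa-mir-sim-{j:04d}" for j in range(p)]
    frame = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    return ExpressionDataset(values=frame, labels=pd.Series(labels, index=sample_ids, name="class"))


def generate_treatments(config: SimulationConfig) -> dict[str, list[tuple[str, str]]]:
    """Draw free-text treatments from the template grammar.

    Each treatment is 2-4 (general, specific) items.  Roughly a third of
    treatments are near-duplicates of an earlier one (one specific method
    swapped), giving the edit-distance landscape that merging needs.
    """
    if config.n_treatments < 1:
        raise ValueError("n_treatments must be >= 1")
    rng = _rng(config, 2)
    n_base = max(1, int(np.ceil(config.n_treatments * 2 / 3)))
    base: list[list[tuple[str, str]]] = []
    for _ in range(n_base):
        n_items = int(rng.integers(2, 5))
        generals = rng.choice(len(GENERAL_TREATMENTS), size=n_items, replace=False)
        items = [
            (GENERAL_TREATMENTS[g], SPECIFIC_METHODS[int(rng.integers(len(SPECIFIC_METHODS)))])
            for g in generals
        ]
        base.append(items)
    treatments = list(base)
    while len(treatments) < config.n_treatments:
        donor = base[int(rng.integers(len(base)))]
        items = list(donor)
        k = int(rng.integers(len(items)))
        general, old_specific = items[k]
        alternatives = [s for s in SPECIFIC_METHODS if s != old_specific]
        items[k] = (general, alternatives[int(rng.integers(len(alternatives)))])
        treatments.append(items)
    return {f"T{i:02d}": items for i, items in enumerate(treatments[: config.n_treatments])}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_outcomes(
    expression: ExpressionDataset,
    treatments: dict[str, list[tuple[str, str]]],
    config: SimulationConfig,
) -> tuple[list[ClinicalRecord], dict[str, str], dict]:
    """Assign demographics and a treatment per patient, then draw outcomes.

    log-odds(remission) = intercept + b_age*z(age) + gender/ethnicity offsets
    + treatment_scale*effect[t] + mirna_main*s + mirna_interaction*s*g[t],
    where s is the mean over (up to) the first five informative features and
    g[t] in {-1, +1} a per-treatment susceptibility sign.  Returns the
    clinical records, the per-patient argmax treatment (the planted "best"),
    and the planted treatment parameters.
    """
    rng = _rng(config, 3)
    coef = config.outcome_coefficients
    treatment_ids = sorted(treatments)
    n = expression.n_samples

    # Planted effects live at the granularity of near-duplicate groups:
    # treatments whose canonical strings sit within edit distance 25 of each
    # other (the merge rule downstream) share one effect, so the planted
    # "best treatment" stays well defined after catalog merging.
    from .treatments import canonicalize, distance_matrix

    canon = [canonicalize(treatments[t]) for t in treatment_ids]
    D = distance_matrix(canon)
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_groups, group_of = connected_components(csr_matrix(D < 25), directed=False)
    group_effects = np.linspace(-1.0, 1.0, n_groups) if n_groups > 1 else np.zeros(1)
    rng.shuffle(group_effects)
    group_suscept = np.array([1.0 if g % 2 == 0 else -1.0 for g in range(n_groups)])
    effects = group_effects[group_of]
    suscept = group_suscept[group_of]

    # The prognostic signature is a patient-level signal: it averages
    # features *without* class mean shifts (the tail of the feature list),
    # so the cancer-type covariate cannot proxy it.  Scaled to unit
    # variance so the outcome coefficients are in logit units.
    n_sig = min(5, max(1, config.n_features - config.n_informative))
    sig_features = expression.feature_ids[-n_sig:]
    signature = np.nanmean(expression.values[sig_features].to_numpy(), axis=1)
    signature = np.nan_to_num(signature, nan=0.0) * np.sqrt(n_sig)

    ages = np.clip(rng.normal(60.0, 10.0, size=n), 20.0, 90.0)
    genders = rng.choice(len(GENDERS), size=n)
    ethnicities = rng.choice(len(ETHNICITIES), size=n)
    gender_offsets = np.array([-1.0, 1.0]) * coef.gender
    ethnicity_offsets = coef.ethnicity * np.linspace(-1.0, 1.0, len(ETHNICITIES))
    assigned = rng.integers(len(treatment_ids), size=n)
    followups = rng.integers(300, 2000, size=n)

    base_logit = (
        coef.intercept
        + coef.age * (ages - 60.0) / 10.0
        + gender_offsets[genders]
        + ethnicity_offsets[ethnicities]
        + coef.mirna_main * signature
    )
    treat_term = coef.treatment_scale * effects[assigned] + coef.mirna_interaction * signature * suscept[assigned]
    remission = rng.random(n) < _sigmoid(base_logit + treat_term)

    # planted best = argmax over treatments of the treatment-dependent term
    all_terms = (
        coef.treatment_scale * effects[None, :]
        + coef.mirna_interaction * signature[:, None] * suscept[None, :]
    )
    best_index = np.argmax(all_terms, axis=1)  # ties -> lowest index

    records = []
    best: dict[str, str] = {}
    for i, pid in enumerate(expression.sample_ids):
        records.append(
            ClinicalRecord(
                patient_id=pid,
                gender=GENDERS[genders[i]],
                age=float(ages[i]),
                ethnicity=ETHNICITIES[ethnicities[i]],
                cancer_type=str(expression.labels.loc[pid]) if expression.labels is not None else None,
                treatment_id=treatment_ids[assigned[i]],
                outcome="remission" if remission[i] else "recurrence",
                followup_days=int(followups[i]),
            )
        )
        best[pid] = treatment_ids[best_index[i]]

    planted = {
        "treatment_effects": dict(zip(treatment_ids, effects)),
        "susceptibility": dict(zip(treatment_ids, suscept)),
        "signature": pd.Series(signature, index=expression.sample_ids),
        "signature_features": sig_features,
    }
    return records, best, planted


def generate_cohort(config: SimulationConfig, raw_scale: bool = False) -> SyntheticCohort:
    """Generate the full cohort: expression, treatments, clinical outcomes."""
    expression = generate_expression(config, raw_scale=raw_scale)
    treatments = generate_treatments(config)
    records, best, planted = generate_outcomes(expression, treatments, config)
    informative = expression.feature_ids[: config.n_informative]
    return SyntheticCohort(
        expression=expression,
        clinical=records,
        treatments=treatments,
        true_informative_features=informative,
        true_best_treatment=best,
        planted=planted,
    )
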