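"""Generate a synthetic pan-cancer cohort and inspect its planted structure.

The generator emulates a TCGA-like cohort: multiple tumor classes with
uneven sample counts, class-separating miRNA features, systemic (class-
independent) missingness, free-text treatments, and a binary
remission/recurrence outcome tied to clinical covariates, treatment and a
planted miRNA signature.
"""

import numpy as np

from mirpan import SimulationConfig, generate_cohort

config = SimulationConfig(
    n_classes=5,
    samples_per_class=(80, 120, 45, 200, 60),
    n_features=150,
    n_informative=25,
    class_effect_size=2.0,
    missing_feature_fraction=0.4,
    missing_rate_within_feature=0.3,
    n_treatments=8,
    seed=0,
)
cohort = generate_cohort(config)

expr = cohort.expression
print(f"expression matrix: {expr.n_samples} samples x {expr.n_features} miRNA features")
print(f"class counts:\n{expr.labels.value_counts().sort_index().to_string()}")
frac = expr.missing_fraction()
print(f"features with any missingness: {(frac > 0).sum()} "
      f"(max missing fraction {frac.max():.2f})")
print(f"clinical records: {len(cohort.clinical)}; "
      f"treatments in catalog: {len(cohort.treatments)}")
remission = np.mean([r.outcome == 'remission' for r in cohort.clinical])
print(f"cohort remission rate: {remission:.2f}")
print(f"planted informative features (first 5): {cohort.true_informative_features[:5]}")

# The planted per-patient best treatment is the generator's ground truth for
# the recommendation stage; here we just show its marginal distribution.
best_counts = {}
for t in cohort.true_best_treatment.values():
    best_counts[t] = best_counts.get(t, 0) + 1
print(f"planted best-treatment distribution: {dict(sorted(best_counts.items()))}")
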