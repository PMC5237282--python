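"""Two-stage feature selection on a cohort with planted informative features.

Stage 1 screens by the best one-vs-rest Pearson correlation with the class
labels; stage 2 runs recursive feature elimination with a linear-SVM
weight ranking down to a fixed budget.  With 20 informative features
planted among 200, the 20-budget selection should recover nearly all of
them.
"""

from mirpan import SimulationConfig, generate_cohort, select_features

config = SimulationConfig(
    n_classes=4, samples_per_class=(50,) * 4, n_features=200, n_informative=20,
    class_effect_size=3.0, missing_feature_fraction=0.0, seed=2,
)
cohort = generate_cohort(config)

result = select_features(
    cohort.expression.values, cohort.expression.labels,
    threshold=0.1, budget=20, seed=2,
)
print(f"stage 1 (correlation screen) kept {len(result.stage1_features)} of 200 features")
print(f"stage 2 (RFE) kept the budgeted {len(result.stage2_features)}")
truth = set(cohort.true_informative_features)
hits = truth & set(result.stage2_features)
print(f"planted informative features recovered: {len(hits)}/20")
top = sorted(result.scores, key=result.scores.get, reverse=True)[:3]
print("top screening scores:", {f: round(result.scores[f], 3) for f in top})
# A recovery near 20/20 means the elimination ranking tracks the features
# that actually separate the classes.
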