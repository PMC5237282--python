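# Methods

This note documents the models and procedures implemented in `mirpan`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohorts do and do not establish.

## Data model

Expression data is a samples × miRNA matrix with `NaN` marking missing
measurements; the observed mask is derived from the values, so the two
cannot disagree. Clinical records carry gender, age, ethnicity, cancer
type, a treatment reference, a binary remission/recurrence outcome and
follow-up days; the outcome is only meaningful at ≥ 300 days of
follow-up, which the eligibility filter enforces.

## Preprocessing

Order: missingness filter → k-NN imputation → log transform →
standardization.

* **Missingness filter** (`missing_threshold`, default 0.2): a feature is
  removed when its missing fraction is *strictly greater* than the
  threshold; a feature missing in exactly 20% of samples is retained.
  Removed feature ids are returned as provenance.
* **k-NN imputation** (`knn_k`, default 10): a missing entry is the
  unweighted mean of that feature over the k nearest samples. Nearness is
  plain Euclidean distance on the features both samples observe;
  candidate neighbours must observe the target feature; distance ties are
  broken by sample order. A sample with no mutually observed features
  falls back to the feature mean and is logged. The defaults (k = 10,
  unweighted averaging) follow common practice for expression-matrix
  imputation; distances over partially observed vectors are *not*
  rescaled by the overlap size, which keeps the hand-checkable toy
  semantics exact.
* **Log transform** (`log_base` ∈ {2, e, 10}, default 2; `log_offset`,
  default 1): elementwise log(value + offset); a nonpositive shifted
  value is an error naming the offending entry. The generator's output is
  already on a log-like (Gaussian) scale, so pipelines on synthetic data
  either use `raw_scale=True` at generation or skip the offset.
* **Standardization**: per-feature z-scoring. Statistics can be fit and
  applied in one step (global mode — appropriate for an external dataset
  standardized on itself) or fit on a training fold and applied to
  held-out data (the cross-validation default, preventing leakage).
  Zero-variance features are dropped during fitting and recorded.

Whether log transformation should precede or follow imputation is not
determined by the data model; the implemented order (impute, then log) is
a configuration choice exposed in `PreprocessConfig`.

## Two-stage feature selection

Stage 1 scores each feature by max over classes of the absolute Pearson
correlation with the one-vs-rest class indicator (point-biserial
correlation), retaining scores ≥ `threshold` (default 0.1). This is the
natural multiclass reading of "meaningful correlation with the output";
a feature–feature redundancy penalty in the style of full
correlation-based subset selection is deliberately out of scope, with the
screen kept as a pure relevance filter. Constant features score 0.

Stage 2 is recursive feature elimination: each round fits a linear
one-vs-rest SVM (`LinearSVC`), ranks features by the summed squared
weights across classes, and removes the lowest-ranked `step_fraction`
(default 0.1, at least one feature) until exactly `budget` features
remain (default 60). The sum-of-squares ranking is the standard
margin-based criterion for multiclass linear SVMs. Internal 3-fold CV
accuracy per round can be recorded. Elimination uses the linear ranking
even when the downstream classifier is radial-kernel, because
model-based ranking needs explicit weights.

Both stages run inside each training fold of a cross-validation; the
intersection of per-fold stage-2 selections, ordered by mean within-fold
rank, is the reported "common features" set.

## Diagnosis

`repeated_stratified_cv` (defaults: 10 folds × 10 repeats) fits
standardization statistics — and, when requested, the full two-stage
selection — on each training portion only, and aggregates all test-fold
predictions into a confusion matrix with **rows = predictions, columns =
truth**. Stratified folds are used because realistic cohorts have class
counts as low as a few dozen. Metrics:

* overall accuracy = trace / total;
* Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the marginals; a
  degenerate matrix with p_e = 1 is defined as κ = 0;
* per-class one-vs-rest sensitivity TP/(TP+FN) and specificity
  TN/(TN+FP); a class absent from the truth margin has *undefined* (NaN)
  sensitivity, not zero.

Classifier families: linear and radial SVM (radial width from the median
pairwise-distance heuristic when not given), random forest, LDA, Gaussian
naive Bayes, kNN, and a logistic model tree implemented as a shallow
decision tree with multinomial logistic models in the leaves (leaf class
priors when a leaf is single-class). Probability outputs for SVMs come
from sigmoid (Platt) calibration fit on internal training folds.
Normal-tissue samples from different organs can be pooled into a single
"Normal" class before classification.

## Developmental tree

The tree is a rooted hierarchy with stage annotations: 1 = germ layer
(endoderm, mesoderm, ectoderm), 2 = intermediate lineage (gut tube,
lateral-plate/intermediate mesoderm, neural tube, neural crest, surface
ectoderm), 3 = tissue/organ, 4 = cancer type (leaf). A bundled JSON
encodes 21 TCGA cancer types; any tree in the same format is accepted and
validated (single root, every leaf reaches an ancestor at each stage).

Two evaluation paths exist and are reported separately: retraining a
classifier on stage-coarsened labels, and coarsening leaf-level
predictions and truths after the fact. The second path carries an exact
guarantee — mapped accuracy ≥ leaf accuracy for every prediction vector,
since coarsening merges labels and can only turn errors into agreements,
never the reverse. The improvement is largest when confusions are
intra-branch (developmentally related cancers), which is the
scientifically interesting regime.

## Treatment space

* **Canonicalization**: each (general, specific) item becomes
  `"general, specific;"` after lowercasing and whitespace normalization;
  items are sorted lexicographically and concatenated. Bag semantics:
  input order never changes the output.
* **Levenshtein distance**: standard O(mn) dynamic program over
  insertions, deletions, substitutions, at character level — treatments
  are compared as strings, not token lists.
* **Merging** (threshold 25, strict): single-linkage — two treatments
  share a cluster iff connected by a chain of pairs at distance < 25.
  The representative is the most frequent member, ties broken by the
  lexicographically smallest canonical string. Canonical-string
  deduplication is implicit (distance 0 always merges). Cluster count is
  non-increasing in the threshold.
* **Cox scaling**: the default `classical` mode is Torgerson scaling
  (double-centre −½D², eigendecompose, top three nonnegative eigenpairs,
  coordinates = eigenvectors × √eigenvalues; missing nonnegative
  eigenpairs are zero-padded and logged), the algorithm behind R's
  `cmdscale`. A plain signed-difference objective Σ(ldist − dist) is
  unbounded below and therefore ill-posed; the `stress` mode instead
  minimizes the squared stress Σ_{i≠j}(ldist(i,j) − ‖P_i−P_j‖)² by SMACOF
  majorization from the classical start (convergence at relative stress
  change < 1e-8 or 500 iterations; the per-iteration trajectory is
  recorded and is non-increasing by construction). Coordinates are fixed
  to a canonical orientation — axes ordered by eigenvalue, each axis's
  largest-magnitude coordinate made positive — so serialized catalogs are
  bit-reproducible.

## Prognosis and recommendation

* **Eligibility**: complete clinical record, follow-up ≥ 300 days, then
  ≥ 5 records per cancer type and ≥ 5 per unique (merged) treatment,
  applied iteratively to a fixed point — dropping a sparse treatment can
  push a cancer type below the minimum, so a single pass is not enough.
  Every drop is logged with its reason.
* **Feature vector** (fixed, documented order): z-scored miRNA block
  (by default the diagnostically selected features; configurable),
  z-scored age, one-hot gender, one-hot ethnicity, one-hot cancer type,
  and the treatment cluster's three Cox coordinates z-scored with
  training statistics — the coordinate block is standardized like every
  other numeric feature so no block dominates kernel distances. Unseen
  categories at apply time yield an all-zero one-hot block.
* **SMOTE** (k = 5): the minority class is raised to the majority count;
  each synthetic sample is x + u·(x′ − x) with u ~ U(0,1), x a random
  minority sample and x′ one of its k nearest minority neighbours.
  Synthetic samples are confined to the training partition by
  construction. A singleton minority is an error.
* **Training**: 75–25 split stratified on outcome; the model (calibrated
  radial SVM by default) fits on the SMOTE-balanced training portion and
  is evaluated on the untouched test portion. An ablation without the
  miRNA block is fitted and reported alongside. Recurrence is the
  positive ("disease") class for sensitivity/specificity naming.
* **Recommendation**: for each treatment cluster, the patient's feature
  vector is rebuilt with that cluster's coordinates and scored; clusters
  are ranked by remission probability, ties broken by ascending cluster
  id, making the result independent of catalog enumeration order.
* **Self-training** (threshold 0.95): unlabeled samples whose maximum
  predicted class probability *strictly* exceeds the threshold are added
  with their pseudo-labels and the model refits on the union; a candidate
  at exactly 0.95 is rejected, original labels are never altered, and
  zero admissions is a valid no-op. Updates run on demand (an explicit
  call / CLI command), not on a timer.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* Gaussian unit-variance features on a log-like scale; the first
  `n_informative` features carry ±`class_effect_size` mean shifts under
  class-specific sign patterns (with `raw_scale=True` the matrix is
  exponentiated to strictly positive values so the log transform
  applies);
* systemic missingness: a fraction of features is missing at one rate
  uniformly over samples, independent of class;
* treatments drawn from a ~10 × 15 "general, specific" template grammar,
  2–4 items each, with deliberate near-duplicates (one specific swapped)
  to exercise merging;
* demographics: two genders, four ethnicity groups, age ~ N(60, 10²)
  truncated to [20, 90] — plausible cohort marginals, all configurable;
* outcomes: Bernoulli with log-odds = intercept + age, gender and
  ethnicity terms + a per-treatment effect + a miRNA signature main
  effect + a signature × treatment interaction. Planted treatment
  effects live at the granularity of near-duplicate groups (treatments
  within merge distance share one effect), so the planted "best
  treatment" remains well defined after catalog merging. The signature
  averages features *without* class shifts, scaled to unit variance, so
  it is a patient-level signal that the cancer-type covariate cannot
  proxy — this is what makes the miRNA-ablation contrast identifiable.

The per-patient argmax of the treatment-dependent log-odds terms is
recorded as the planted best treatment.

What the generator does **not** model: miRNA co-expression covariance,
sequencing-depth or batch effects, platform differences, censoring, or
treatment assignment correlated with covariates (assignment is uniform).
Passing tests therefore demonstrate algorithmic correctness and
recoverability of planted structure under the stated noise model, not
clinical performance on real cohorts.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately compact cohorts chosen to make
the planted structure decisively recoverable: 4–5 classes × 50 samples
for selection/diagnosis recovery (effect size 3), 21 × 30 at effect 0.9
for tree climbing (leaving visible intra-branch confusion), 500–750
patients for prognosis and recommendation. Cross-validation in these
runs uses 3–5 folds with 1–2 repeats; the protocol supports the
conventional 10 × 10 unchanged. Other numerics: imputation distance ties
break by sample order; argmax prediction ties break toward the lowest
class index; eigenvalue thresholds treat λ ≤ 0 as unusable axes;
`LinearSVC` runs with `dual=False` and a fixed random state for
reproducibility; all stochastic stages accept explicit seeds and derive
independent streams per stage.

## Known limitations

* The recommendation score is a calibrated SVM probability; within a
  confidently classified region, calibrated probabilities order
  treatments by margin distance, which tracks empirical remission rates
  only approximately. Recovery is reliable when the planted best
  treatment is distinctly the highest-remission option, and degrades when
  several treatments are near-equivalent.
* The logistic-model-tree family is a compact reimplementation (tree +
  per-leaf logistic models), not a port of any particular reference
  implementation.
* The eligibility filter treats "unique treatment" as the merged cluster
  when a catalog is supplied, else the raw treatment id.
* Character-level edit distance is sensitive to string length; long
  treatment lists dominate the metric. This mirrors the canonical-string
  design rather than correcting it.
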