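# Methods

This note documents the modelling choices in `nanoqsar`: what each stage
assumes, which knobs matter, what the synthetic-data generator does and
does not emulate, and where the design was genuinely open.

## Data model and splitting

A *treatment* is one (nanoparticle, concentration) row with numeric
atomistic descriptors, optionally categorical ones (e.g. a coating
label), and a binary endpoint with positive class "high effect".
Interdependent descriptors are declared in the schema as
`difference(a, b)` or `ratio(a, b)` rules over other columns; rules may
not chain, which keeps the dependency graph acyclic by construction.

Stratified splitting holds out `round(fraction × class_count)` rows per
class, with halves rounded away from zero. This remainder policy is what
makes a 110-row table with 73/37 classes split into a 33-row blind set
(22/11), then a 20-row test set (13/7) and a 57-row training set under
the default 30% / 25% fractions. All random draws come from named child
streams of one global seed (`_rng.child_seed`), so each stage is
independently reproducible and insensitive to the others.

Normalisation is the z-score with sample (n−1) standard deviation,
fitted on training rows only; zero-spread columns are flagged and passed
through unchanged in both directions, keeping the forward/inverse round
trip an exact identity. Sample variance/sd is used everywhere (filters
included) for internal consistency.

## Oversampling

Both oversamplers operate on z-scored, non-derived, complete numeric
columns; Euclidean kNN with k = 5 by default, ties at equal distance
broken by the lowest row index. SMOTE generates
`round(balance_target · N_maj) − N_min` synthetic rows (default: exact
balance); ADASYN computes per-minority-row difficulty
r_i = (majority among k nearest in the full set)/k and apportions
G = round(balance_target · (N_maj − N_min)) by largest remainder, so the
total is exactly G whenever the weights allow. If no minority row has a
majority neighbour the weights degenerate to uniform with a warning. If
k exceeds N_min − 1 it is clamped with a warning rather than failing —
these datasets are small and a hard error would be unhelpful.

Categorical values of a synthetic row are copied from its seed row.
Original rows pass through the pipeline bit-identical: derived columns
are recalculated only on synthetic rows, after denormalisation, so the
stored originals are never touched by float round trips.

## Utility assessment

pMSE is computed by leave-one-out cross-validation: per fold the
low-variance filter (0.2) and Spearman filter are refitted on the n−1
training rows, columns z-scored, and an unregularised logistic
regression (lbfgs, max 100 iterations, tol 1e−6) predicts the held-out
row's provenance. Folds that fail to converge keep the last iterate's
probability and are counted in the report. Two thresholds deliberately
coexist: the Spearman cut is 0.9 inside the pMSE model and 0.95 in the
modelling filter cascade; both are separate config keys
(`spearman_threshold_pmse`, `spearman_threshold_model`).

By default all rows of the oversampled table enter the LOO model, since
N in the pMSE formula is the row count after oversampling; a
`population="minority"` switch restricts it to the oversampled class
(original minority + synthetic), where synthetic rows actually live.
Both modes are tested. The oversampler with the lower pMSE wins; an
exact tie goes to ADASYN as the density-adaptive method. KL divergence
(10 equal-width bins over the pooled range, natural log, additive
smoothing 1e−9 on empty bins) and the 1-D Wasserstein distance are
reported per descriptor but never override pMSE.

## Filtering

The cascade order is fixed and test-enforced: variance → Spearman →
information gain → dedupe → z-score. Variance is computed on the raw
scale (the filter is scale-dependent by construction, matching the
workflow order); exact constants drop at any threshold. The Spearman
filter scans columns in schema order and drops the later column of any
pair with |ρ| ≥ threshold against an already-kept column; dropped
columns cannot trigger further drops. Information gain uses base-2
entropy with equal-frequency discretisation into min(10, #distinct)
bins — equal-frequency is robust to the skewed, log-spaced
concentration grid; the bin count is configurable. Rows identical on
(selected descriptors + endpoint) collapse to the first occurrence;
rows identical on descriptors but conflicting on the endpoint are all
kept with a warning, since collapsing would silently pick a label.

## AutoML

Random search samples hyperparameter combinations uniformly without
replacement (a space smaller than the budget is simply exhausted),
scores each by mean Cohen's kappa over stratified 5-fold CV, and stops
after `max_iter` = 10 candidates or `patience` = 5 consecutive
non-improvements. A combination that fails to fit in any fold scores
kappa = −1. Fold-level held-out labels and predictions are stored so the
reported mean is recomputable exactly.

Search ranges: trees ∈ {25, 50, 100, 200, 400}; depth ∈ {2..8}; minimum
node sizes ∈ {2, 4, 8, 16, 32}; XGBoost eta ∈ {0.05, 0.1, 0.2, 0.3}
(tree count fixed at 100); hidden layers ∈ {1, 2} × neurons ∈
{5, 10, 15, 20}; SGD-logistic step size ∈ {0.001, 0.01, 0.1}; naive
Bayes floor on a log grid 1e−4..1e−2.

Two family interpretations were open and are resolved as follows. The
logistic-regression family tunes a literal *step size*, so it is fitted
by SGD on the log loss with a constant learning rate — the only
formulation in which that hyperparameter exists. The naive-Bayes
*default probability* is implemented as a floor on each per-feature
Gaussian class-conditional density before the naive product
(`_FlooredGaussianNB`), which is the standard role of such a parameter:
a fallback probability that stops a single outlying feature value from
zeroing out a class posterior.

Model selection on the test set ranks by MCC, then kappa, then accuracy
— MCC being the most balanced single summary of a 2×2 table. The
classification threshold is 0.5 on P(high) for all families.

## Validation

Cohen's kappa is computed as 2(TP·TN − FP·FN) / [(TP+FP)(FP+TN) +
(TP+FN)(FN+TN)] and MCC with its usual four-factor denominator;
undefined ratios (zero denominators) are reported as missing with a
warning rather than coerced to 0. Reported tables round to 2 decimals;
JSON artifacts keep full precision. Y-randomisation permutes the
training endpoints (class counts preserved), re-runs oversampling,
filtering and tuning of the winning family, and scores the untouched
test set; by default hyperparameters are re-tuned every round ("all
modelling steps repeated"), with a `retune=False` switch to freeze them
for speed. When a shuffled round's MCC is undefined (the refit predicts
a single class), summaries treat it as 0 — no association.

## Applicability domain

Leverage and similarity work on z-scored selected descriptors without an
intercept column: k in h* = 3k/N is the number of descriptors in the
model, and centring makes h a literal distance from the training
centroid. The bounding box is evaluated on the raw scale (range checks
are scale-invariant, so this is presentational). (X'X)⁻¹ falls back to
the pseudo-inverse when singular; N < k additionally warns. The AD is
fitted on the oversampled modelling training set by default — that is
the set the classifier actually saw — with `ad_on_oversampled=False`
available. Cosine similarity is computed on the same z-scored
coordinates as the kNN distances, for consistency. The Moderate band
(score = 0.5) is detected with tolerance 1e−9 so float arithmetic cannot
misclassify it. With default weights (0.2, 0.3, 0.5) the attainable
scores are exactly {0, 0.2, 0.3, 0.5, 0.7, 0.8, 1.0}.

## Synthetic-data generator

The generator emulates the statistical shape of a small NP
dose–response study: 11 NPs × 10 log-spaced concentrations
(0.1–100 µg/mL) = 110 treatments at 34% "high effect". Per-NP base
descriptors follow a one-factor model with loading
√(correlation_strength) (default 0.6), inducing realistic
inter-descriptor correlation; at strength 1.0 two columns become exact
duplicates to exercise the redundancy paths. Difference-type derived
columns pair consecutive base descriptors. The endpoint is the top
`round(imbalance × n)` rows of a latent score

    1.8 · z(log10 conc) + 1.2 · z(signal descriptor) + noise_sd · ε,

with noise_sd = 0.5 — dose dominates, one descriptor carries a
secondary signal, and the label is monotone in concentration at fixed
descriptors and noise. The weights were set once so that the dose term
clearly leads the information-gain ranking while the problem remains
imperfectly learnable, which is the regime the workflow is built for.

What the generator does **not** emulate: real descriptor physics (no
force-field structure, no size/shape semantics), inter-NP chemistry
families, plate/batch effects, or label noise from the upstream
screening pipeline. Passing tests therefore demonstrate that the
workflow recovers a planted signal of realistic shape and strength —
not that any real dataset's printed values are reproduced; data-bound
quantities from the original study (its pMSE values, gain scores,
per-round randomisation rows, blind-set AD counts) require the
deposited dataset and are covered here by property-based bounds
instead. An exported CSV of that dataset can be run through the same
pipeline via `PipelineConfig(input_csv=..., schema_yaml=...)`.

## Problem sizes

The default end-to-end run operates on 110 treatments: a 76-row
oversampled training set, 7 families × ≤ 10 candidates × 5 folds in the
search, ~76 LOO folds per pMSE evaluation, and 10 Y-randomisation
rounds with full re-tuning of the winning family — about a minute on
one CPU. These sizes are the package's test-bed defaults; all of them
scale through `PipelineConfig` and `FixtureConfig`.

## Known limitations

* pMSE's LOO logistic regression is unregularised; on nearly separable
  provenance problems individual folds may not converge (counted and
  reported, last iterate used).
* The greedy Spearman filter is order-dependent by design; a different
  schema order can keep a different representative of a correlated
  group.
* ADASYN's difficulty weights use the standard full-set neighbourhood;
  implementations differ on this point, and minority-only
  neighbourhoods would shift the allocation.
* The AD treats categorical descriptors only through the bounding-box
  label check; they carry no leverage or similarity contribution.
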