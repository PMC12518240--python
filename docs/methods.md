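# Methods

This note documents the statistical procedure implemented by `epheclass`,
the defaults it ships with, the choices that were genuinely open, and what
the synthetic tests do and do not establish about real data.

## Compositional preprocessing

Amplicon count tables carry only relative information: sequencing depth is a
nuisance parameter, so all analysis happens on the simplex. The pipeline
first discards samples with fewer than `min_total_counts` (default 2,500,
inclusive) total counts — below that depth relative frequencies of all but
the dominant taxa are too noisy to be useful. A pseudocount (default 1) is
added to every cell so log-ratios are defined, each row is closed to
relative frequencies, and only the `top_k_features` (default 1,500) features
with the highest **mean relative frequency across all samples** are kept.
Rare taxa are dropped both for numerical stability and because abundant taxa
are the more robust indicators of community shifts. Two details matter:

* The ranking statistic for "most abundant" is mean relative frequency;
  total counts or prevalence would also be defensible, so the statistic is
  deliberately isolated in `top_abundant_features` and ties are broken
  toward the lower feature id to keep the cut deterministic.
* Retained columns keep their values (no re-closure). The subsequent CLR is
  scale-invariant per row, so the lost closure constant is irrelevant.

The train/test split (default 70/30) is stratified by class with per-class
floor + largest-remainder rounding, so the global train fraction is met
exactly and each class deviates from `round(frac * n_class)` by at most one
sample. The abundance cut is computed on the full dataset before the split,
matching the stage order of the procedure this package implements; this
leaks a small amount of rank information into the test set, so a strict
post-split mode is available via `RunConfig.topk_on_train_only`.

The CLR transform `x ↦ ln(x / g(x))` is applied row-wise; rows map to
zero-sum vectors and the transform never mixes samples, so it can be applied
before or after any row subsetting without leakage.

## Compositional CutMix

Class imbalance is handled, when requested, by synthesizing minority-class
training compositions: two parents are drawn uniformly with replacement from
the same (class, stratum) cell, a feature mask is drawn i.i.d.
Bernoulli(`p_mask`, default 0.5), the child takes each feature from one
parent or the other, and is re-closed to sum 1. The child is therefore
strictly positive whenever its parents are and never mixes classes or strata.
Each stratum is topped up to its own majority-class count. The mask
probability and the single global re-closure are the symmetric, simplest
members of this augmentation family; a two-part λ-weighted renormalisation
would also be consistent with the idea but is not implemented. Augmentation
operates in composition space *before* CLR, and — during cross-validation —
is re-planned inside each training fold only. Test data are never augmented.

## Consensus recursive feature elimination

RFE removes, per iteration, the `max(1, floor(0.05 · current))` features
with the smallest importance (impurity importance for the random forest,
summed absolute coefficients for the linear SVM and logistic regression),
truncating the last removal to land exactly on the target. The SVM is
linear-kernel by necessity: RFE needs per-feature coefficients.

A single shared target *t* is scanned upward from *t = NSF*; at each *t* the
three survivor sets are intersected and the scan stops at the first *t*
whose intersection has exactly NSF features. Because re-running the
elimination from scratch at every *t* would repeat almost all fits, each
estimator's elimination path is computed once down to NSF, recording each
fit's importance ranking; the survivor set at any larger *t* is then
reconstructed from the recorded rankings. This is fit-for-fit identical to a
standalone run at *t* (the two runs only diverge at the final truncated
removal, which is replayed from the recorded ranking). A consequence of the
shared path is that survivor sets are nested in *t*, so intersection sizes
are non-decreasing — when the size jumps from, say, 6 to 8, a 7-feature
consensus is unattainable and the scan raises an error carrying its full
trace rather than silently returning a wrong size. `t_max` defaults to
`min(200, n_features)`.

Estimator hyperparameters during RFE are fixed defaults; tuning happens
later, on the reduced table. Feature selection sees training rows only.

## Base models and tuning

Five families span the pool: kNN, random forest, SVM, XGBoost and MLP.
Grids cover each family's commonly tuned knobs (neighbour count and vote
weighting; tree count, depth, leaf size; kernel and C; depth and learning
rate; hidden sizes and weight decay) and are fully config-overridable;
`small_grids()` provides one-point grids for quick runs. Selection is
exhaustive grid search scored by mean ROC AUC over stratified 10-fold CV,
ties resolved by grid order. AUC is the tuning metric because the cohorts
this pipeline targets are imbalanced and both error directions are costly.
SVM probabilities come from cross-validated Platt-style calibration.

Tuning runs on the (augmented) training set as a whole. Re-planning the
augmentation inside every tuning fold as well would require coupling the
grid search to fold identity; the per-fold re-augmentation is instead
applied where it affects reported numbers, in the evaluation CV loop.

## Dynamic ensemble selection

For a query *x*, the region of competence is its *k* (default 7) nearest
DSEL samples by Euclidean distance in the consensus-reduced CLR space, ties
broken by DSEL index. With the binary correctness of each base model on each
neighbour:

* **DES-P** keeps models whose region accuracy strictly exceeds 1/2 (a
  random binary classifier); "equal to chance" is not competence.
* **KNORA-E** keeps models correct on *all* neighbours, dropping the
  farthest neighbour and retrying while none exists.
* **KNORA-U** keeps models correct on ≥ 1 neighbour, weighted by their
  number of correct neighbours.
* **DES-C** partitions DSEL by seeded k-means (default 5 clusters); within
  the query's nearest cluster it keeps the `ceil(0.5 · n_models)` most
  accurate models and greedily retains the `ceil(0.33 · n_models)` most
  mutually diverse among them, where pairwise diversity is one minus the
  double-fault rate (fraction of cluster samples both models misclassify),
  seeding the greedy pass from the most accurate model.

If a rule selects nothing even after its own shrinking/fallback steps, the
whole pool votes with uniform weights and the decision is flagged — this
keeps decisions total and matches common DES practice. Selected models cast
weighted hard votes (a model votes positive when its class-D probability is
≥ 0.5); a vote tie goes to the side favoured by the weighted mean
probability, and an exact residual tie to the negative class. The ensemble
*score* — used for all AUC computations — is the weighted mean class-D
probability, so it always lies in [0, 1].

The region size *k* can be tuned over `{3, 5, 7, 9, 11}` by cross-validated
AUC within DSEL (each fold of DSEL serves as queries against the rest),
smallest *k* winning ties; by default *k* stays fixed at 7.

Two DSEL conventions are implemented. During the evaluation CV, each fold's
validation part doubles as DSEL and as the scoring queries — a query is then
its own nearest neighbour, which makes CV numbers mildly optimistic; this
mirrors the 10%-validation convention of the procedure being implemented and
is confined to CV. Final test-set numbers use a clean, disjoint DSEL: 10% of
the *un-augmented* training rows are carved out stratified, base models are
refit on the remaining 90% (re-balanced if augmentation is on), and test
queries are scored against that carve-out. Carving DSEL before augmentation
keeps synthetic rows out of the competence reference set.

## Evaluation and ROC comparison

Metrics are F1, precision, recall, accuracy (positive class = `D`,
zero-denominator conventions map undefined ratios to 0) and trapezoidal ROC
AUC with half-credit for ties. CV metrics pool the out-of-fold predictions
before computing a single number per model — per-fold AUC at these fold
sizes is too unstable to average meaningfully (a per-fold mode would be a
straightforward extension). Per-NSF tables, an NSF-averaged table and
AUC-vs-NSF line plots are written per run; NSF values whose consensus was
unattainable are logged, skipped and excluded from averages.

Two ROC curves are compared with Venkatraman-style rank permutation tests.
Scores are replaced by ranks; at every cutoff rank the classification error
(false negatives + false positives) of each curve is computed and the
statistic is the summed absolute difference across cutoffs — zero exactly
when the empirical curves coincide, and invariant to monotone score
transformations. The paired null swaps, per sample with probability 1/2,
which curve each of its two rank scores belongs to, jittering unswapped
ranks before re-ranking so swapped-in values interleave exchangeably; the
unpaired variant permutes group membership of pooled records within each
class and integrates the curve difference over a common abscissa. P-values
use the add-one formula `p = (1 + #{perm ≥ obs}) / (1 + B)` with B = 999 by
default, so the smallest attainable p is 1/(B+1) and p = 0 is impossible.
The statistic implementations were cross-checked against an independent R
implementation (pROC) on fixed fixtures; those values are frozen in the unit
tests. Pairwise p-values are reported raw (a Holm adjustment is a one-liner
on the returned table but is not applied by default).

The runner guards the test split: training-only stages assert that no test
sample id reaches them, and an optional `StageAudit` records the ids every
stage consumed so the guarantee can be verified externally.

## Synthetic data generator

The generator emulates the features of real 16S tables that matter to this
pipeline: a shared log-normal base composition with a heavy right tail
(`sigma_base = 1.5`, matching the steep rank-abundance curves of real
communities), per-sample log-normal perturbation (`sigma_sample = 1.0`),
a known set of informative features multiplied by `exp(±effect/2)` per class
before closure, class-independent structural zeros by Bernoulli thinning
(default 30%), uniformly random library sizes, optional class imbalance and
an optional categorical stratum. Counts are multinomial draws, so shallow
samples are noisier — as in real data. Everything is deterministic given the
seed, and the planted feature ids are returned.

Presets fix the study conditions used by the tests: `strong_signal`
(200 × 100, effect 4, balanced), `pd_like` (imbalanced, two strata),
`ibd_like` (larger, sparser, weaker effect) and `null` (effect 0). The null
preset uses 600 samples so that its 180-sample test split estimates a null
AUC with a standard deviation of about 0.04, tight enough for a meaningful
[0.4, 0.6] chance band. The feature-recovery study uses 300 samples × 200
features with 10 planted features at effect 2 — small enough to run in
seconds per seed, large enough that recovery is informative.

What the generator does *not* emulate: phylogenetic correlation between
taxa, batch effects, compositional interactions beyond the planted shifts,
overdispersion beyond multinomial + log-normal mixing, and sequencing error.
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour under controlled signal/null conditions, not expected performance
on any particular real cohort.

## Numerical and reproducibility notes

* All seeds derive from the config: the per-NSF seed is a fixed function of
  (master seed, NSF), so per-NSF work is order-independent; reruns with an
  identical config produce byte-identical tables and manifests (floats are
  written at fixed precision).
* Distance and importance ties are always broken by index; sort operations
  are stable.
* Degenerate inputs fail loudly: empty tables, single-class strata,
  unmappable labels, non-integer or negative counts, pseudocount 0 with an
  all-zero row, k outside [1, |DSEL|].
* Problem sizes in the shipped tests (tables up to 600 × 200, one-point
  grids in the end-to-end checks) were chosen so the full suite runs in
  about ten minutes on a single core while still exercising every branch;
  all sizes are configuration, not constants.

## Known limitations

* The BIOM reader covers the v1 JSON and v2.1 HDF5 count-table layouts but
  ignores embedded observation/sample metadata beyond ids.
* DES-C's accuracy/diversity fractions and cluster count are defaults with
  no tuning support; only the double-fault measure is implemented.
* Selecting the "best" ensemble by average *test* AUC across NSFs — as the
  comparison reports allow — is optimistic model selection; the CV-based
  ranking in the same reports is the methodologically clean default.
* The consensus scan's nested-path optimisation fixes the estimators'
  random states across targets; with freshly seeded estimators per target
  the intersection sizes need not be monotone.
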