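# Methods

`mci-harmonix` implements a tabular-MRI analysis pipeline for separating
stable healthy elders (HC) from initially healthy elders who convert to mild
cognitive impairment within five years (uHC), using hemisphere-merged
FreeSurfer regional volumes. This note documents the models, the synthetic
cohort generator, the numerical choices, and what the test suite does and
does not establish.

## The problem and the pipeline

Regional brain volumes confound the disease signal with head size (ICV), age
and sex. The pipeline therefore proceeds in four stages:

1. **harmonization** — remove (age, sex, ICV) variation by reference-group
   polynomial regression;
2. **feature ranking** — score each region by several univariate criteria and
   derive candidate feature subsets;
3. **classification** — five classifier families tuned by Bayesian
   optimization inside a nested cross-validation loop;
4. **comparison** — N-way ANOVA plus multiple-comparison control over the
   replicated metric values.

## Covariate harmonization

For each volume feature *y* and each sex stratum, an ordinary-least-squares
polynomial surface in (age, ICV) is fitted on the HC rows only:

* `poly11` (default): mu(age, icv) = b0 + b1·age + b2·icv
* `poly22`: adds age², age·icv and icv² terms.

Every subject (HC or uHC) is then corrected with the model of their sex:

* residual: x = y − mu_hat
* z-score: x = (y − mu_hat) / sigma_hat

`sigma_hat` defaults to the observation-level prediction standard deviation,
`sqrt(mse · (1 + x0ᵀ (XᵀX)⁻¹ x0))`, which is what a prediction-interval
routine reports for a new observation; a mean-level variant
(`sqrt(mse · x0ᵀ(XᵀX)⁻¹x0)`) is available through `sd_mode="mean"`.
Only the standard deviation enters the z-score, so no interval confidence
level needs to be chosen.

Numerics: the design columns span ~12 orders of magnitude (1 vs ICV² ≈ 10¹²),
so the solver equilibrates columns to unit norm before a QR factorization and
rescales the coefficients and the Gram inverse afterwards. Rank deficiency is
detected on the equilibrated triangular factor (relative threshold 1e-10).
Z-scoring refuses to divide by a prediction sd below 1e-10. Queries outside
the reference covariate hull are permitted but logged as extrapolation, since
the fitted surface is least reliable where reference points are scarce.

Non-reference rows are never used for fitting and the models are never
refitted on corrected data; refitting on residual-corrected reference data
recovers coefficients statistically indistinguishable from zero (tested).

## Feature ranking and subsets

Five criteria per feature, two-group case:

* one-way ANOVA and Kruskal–Wallis (tie-corrected), scored as −ln p;
* chi-square independence of a discretized copy of the feature
  (default 10 equal-frequency bins on the pooled sample, exposed) vs group,
  scored as −ln p;
* ANCOVA: partial F-test for the group term in
  `value ~ group + age + sex + education + icv` (sex binary-coded);
  collinear covariates are rejected with the offending pair named;
* ReliefF (Kononenko weighting), every observation an anchor, k = 10 nearest
  hits/misses under the Manhattan distance on range-scaled features;
  `diff` for a constant feature is defined as 0, so its weight is exactly 0.

Natural log is the default for −log(p) scores (a `log_base="10"` flag
exists). Because raw scales differ, scores are converted to percentages of
the per-method positive-score total; non-positive scores map to 0%.

Subsets:

* **A** — mean of the four method percentages at or above the median of those
  means ("at or above": ties included, so identical scores select everything);
* **B** — strictly positive ReliefF weight;
* **C** — intersection of all per-criterion selections (per-method percentage
  at/above that method's median for chi-square/ANOVA/Kruskal–Wallis, positive
  ReliefF, rule A, rule D);
* **D** — Bonferroni-adjusted p ≤ 0.05 simultaneously in ANOVA, ANCOVA and
  Kruskal–Wallis.

## Classifiers

Five families behind one fit/predict contract, with the search spaces:

| family | hyperparameters |
|---|---|
| naive Bayes | distribution ∈ {normal, kernel}; kernel ∈ {box, epanechnikov, normal, triangle}; width multiplier ∈ [1e-2, 1e2] (log) |
| KNN | neighbors ∈ [5, 30]; 11 distance functions |
| SVM | kernel ∈ {gaussian/rbf (aliases), linear, polynomial}; kernel scale, box constraint ∈ [0.1, 10] (log) |
| logistic lasso | λ ∈ [1e-3, 10] (log); score transformation (monotone, affects reported scores only) |
| RUSBoost | cycles ∈ [10, 300] (log); learning rate ∈ [0.01, 1] (log); max splits ∈ [1, 64] (log) |

Design choices:

* The kernel naive Bayes and RUSBoost are implemented in this package.
  Kernel NB uses per-class, per-feature univariate KDE,
  `density(x) = (1/(n·w)) Σ K((x−xᵢ)/w)`; the default width is Silverman's
  rule per class and feature, and the tuned parameter is a log-scaled
  multiplier of it — an unbounded positive width would break surrogate
  optimization, and the multiplier keeps the space dimensionless. Gaussian NB
  variances are floored at 1e-9 of the feature variance.
* RUSBoost draws, per boosting cycle, all minority samples plus an equal-size
  uniform undersample of the majority class, fits a leaf-limited decision
  tree with the current boosting weights, and applies the AdaBoost.M1 update
  (shrunk by the learning rate) computed on the full training set. Cycles
  with weighted error ≥ 0.5 terminate boosting.
* Class-imbalance compensation uses the misclassification cost matrix
  [[0, 1], [δ, 0]] with δ = majority/minority cardinality ratio of the
  training fold, realized as class weights (minority δ, majority 1): inside
  the training loss for SVM and the logistic lasso, and exactly at decision
  time through the weighted-risk Bayes rule for naive Bayes and KNN (for
  probabilistic classifiers the two realizations coincide; the NB case is
  verified analytically in the tests). RUSBoost never receives δ — its
  per-cycle undersampling already balances training.
* λ for the logistic lasso multiplies the average per-observation loss, so
  the wrapper maps it to C = 1/(n·λ).
* KNN, SVM and the logistic lasso operate on standardized features (a
  StandardScaler pipeline): the kernel-scale range [0.1, 10] is meaningless
  on raw mm³ columns. NB and RUSBoost see raw features.
* Set-type KNN metrics (hamming, jaccard) are defined on features binarized
  at their training medians; "spearman" ranks queries against the training
  sample. Both choices are documented because the metrics are otherwise
  undefined on continuous volumes.
* SVM scores are signed decision values; probabilistic families report the
  positive-class posterior.

## Evaluation engine

Nested cross-validation: K stratified outer folds (default K = 10; each fold
holds out ~1/K of the data); on each outer-training set a sequential
model-based optimizer minimizes the δ-cost-weighted misclassification rate of
an internal (K−1)-fold cross-validation; the selected configuration is
refitted on the full outer-training data and applied to the holdout. Holdout
predictions pool into one confusion table per replication (fold-averaged
metrics by flag; pooling is the default because per-fold tables at n ≈ 121
are too sparse for stable MCC). The inner-CV performance of the selected
configuration is recorded as the optimism-prone **direct** estimate; the
difference (direct − nested) measures tuning optimism and is positive for
tuned classifiers on noise (tested; with a fixed configuration and no tuning
the gap is ~0 by construction).

The optimizer: an initial random design of max(10, budget/5) points, then a
Gaussian-process surrogate (RBF + white noise, inputs one-hot/log-scaled to
[0, 1], no kernel-hyperparameter restarts) with expected-improvement
acquisition over random candidate draws; non-finite objective values are
imputed at the observed worst, and >50% non-finite evaluations abort. A pure
random-search fallback honors the same contract. The returned point is the
argmin of the *observed* objective.

Monte Carlo: `mc_reps` independent replications (default 20); per-replication
seeds derive deterministically from
`SeedSequence((master_seed, replication, combination_index))`. Balanced mode
draws a fresh majority undersample each replication before nested CV;
imbalanced mode computes δ on each outer-training fold. Failed folds are
logged and counted, never silently dropped.

## Synthetic cohort generator

The generator is the package's study-condition definition, not a test dial.
Each of the 40 default predictors follows

    v = intercept(sex) + age_slope·age + icv_coef·ICV (+ optional quadratics)
        + uhc_effect·1{uHC} + N(0, noise_sd²),   floored at 1 mm³,

with ages uniform on [60, 86] (a truncated-normal mode exists for matching
reported age means), converter ages shifted +3 years (the age confound
harmonization must remove), ICV normal per sex (male 1.55e6, female 1.35e6,
SD 1.2e5 mm³ — typical FreeSurfer eTIV values), education and MMSE drawn with
group-typical means.

Calibration of the 8 effect regions (lateral ventricle, inferior lateral
ventricle, hippocampus, accumbens area, entorhinal, lateral orbitofrontal,
middle temporal, whole-brain segmentation volume): the HC mean and SD equal
the reference-cohort values, `uhc_effect` equals the reported uHC−HC mean
difference, and `noise_sd` is set so that the covariate-adjusted effect size
reproduces the adjusted two-group p-value reported at n = (97, 24) (capped at
0.9·SD where the printed difference alone exceeds the SD, as for the
ventricles). The covariate-explained variance is split 80% ICV / 20% age;
ventricles get positive age slopes, tissue negative. The remaining 32 regions
get literature-plausible means with noise at 75% of the total SD. These
choices were fixed once, before any acceptance measurement.

What the generator does **not** emulate: cross-region correlations (no
covariance structure is reported; noise is independent across regions),
longitudinal trajectories, site/scanner effects, non-Gaussian volume
distributions, and MMSE-diagnosis coupling. Passing tests therefore
demonstrate that the pipeline recovers planted covariate and group structure
of this form — not that it would achieve any particular accuracy on real
cohort data, whose inter-regional correlation alone can change classifier
behavior materially.

## Statistical comparison

Replication-level metric values are compared by N-way ANOVA (type II sums of
squares) over the design factors, pairwise Welch tests with Benjamini–
Hochberg control at 5% FDR (Bonferroni available), and Tukey HSD
(Tukey–Kramer for unequal sizes). Replications are treated as independent
observations; they share data through resampled partitions, so reported
p-values are approximate and the report says so. ANOVA is run on raw metric
values in [0, 1] by default; a logit transform flag exists.

## Problem sizes used by the shipped configuration

The desk-scale configuration (5 outer folds, 5 replications, 30 optimizer
iterations) is the package's default for interactive runs, the test suite
and the results-reproduction script; the reference-scale configuration
(K = 10, 20 replications, 200 iterations) remains available through
`EvaluationConfig`. Simulation-based checks use 50–100 replicates for
recovery/coverage properties and 10–25 for the heavier end-to-end
comparisons.

## Known limitations

* The GP surrogate treats integer parameters as continuous and rounds at
  sampling time; for spaces dominated by categoricals it degrades gracefully
  toward random search.
* MCC of a table with a zero margin is defined as 0 (independence
  convention) and flagged; PPV/NPV/TPR/TNR with zero denominators are 0 and
  flagged. These cases are reachable (a collapsed classifier on imbalanced
  data) and the flag should be checked before interpreting a 0.
* The z-score harmonization divides by a leverage-dependent sd, so corrected
  values at the covariate-hull borders have slightly inflated spread at small
  reference n — the reason residual harmonization is the default.
* Balanced-mode undersampling discards majority data; its variance across
  replications is correspondingly higher.
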