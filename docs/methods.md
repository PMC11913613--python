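# Methods

## Problem setting

The package targets wrapper feature selection for tabular clinical risk
prediction: given a physical-examination cohort with 33 mixed binary and
continuous predictors and a binary pulmonary-nodule label, find the subset
of predictors that maximises the cross-validated accuracy of a chosen
classifier, then use the fitted model for per-subject risk prediction.
The search over the 2^33 candidate subsets is driven by a swarm
metaheuristic, the improved sooty tern optimisation algorithm (ISTOA).

## The optimiser

### Base algorithm (STOA)

Each of N candidates holds a real position vector P in the box-constrained
search space; the objective f is minimised. One iteration applies, per
component (i, j):

- collision avoidance `C = S_A · P`, with `S_A = Cf · (1 − t/T)` decaying
  linearly from `Cf = 2` to 0 over the T-iteration budget;
- convergence toward the incumbent best `M = C_B · (P_best − P)`, with
  `C_B = 0.5 · U(0,1)`;
- spiral attack around the best:
  `P ← (C + M) · (x' + y' + z') · P_best`, where `x' = r sin θ`,
  `y' = r cos θ`, `z' = r θ`, `r = u · e^{−vθ}`, and `θ ~ U[0, 2π)`.

Positions are clamped to the bounds after every move; the incumbent best is
replaced only by a strictly improving candidate, so the best-so-far curve
is non-increasing by construction.

Two numerical points deserve emphasis. First, the spiral radius must
*decay* with the angle: with a growing radius `e^{+vθ}` the attack factor
`s = r(sin θ + cos θ + θ)` satisfies `s ≥ 1` for every θ in `[0, 2π)`
(the bracket has minimum ≈ 2.14 at θ = π and equals 1 at θ = 0), so the
multiplicative update can only inflate positions into the clamp and the
search stalls; the contracting form reproduces the convergence behaviour
reported for this family of algorithms. Second, the multiplicative
coupling to `P_best` gives STOA a strong bias toward the coordinate
origin: it reaches machine zero on origin-centred benchmarks but performs
poorly when the optimum lies elsewhere (e.g. Schwefel 2.26). This is a
known property of the base algorithm, and one of the motivations for the
enhanced variant.

### Enhancements (ISTOA)

1. **Bernoulli chaotic initialisation.** The two-branch shift map
   `x ← x/(1−λ)` for `x < 1−λ`, `x ← (x−(1−λ))/λ` otherwise, with
   `λ = 0.4`, produces an ergodic low-discrepancy stream used to fill the
   initial population (one continuing stream, mapped affinely onto the
   bounds). Iterates are nudged by 1e−12 if they hit a branch boundary,
   which would otherwise freeze the orbit.
2. **Cauchy mutation of the best.** With per-iteration probability 0.5 the
   incumbent best is perturbed multiplicatively,
   `X_new = X_best + X_best ⊙ c`, with independent standard-Cauchy
   components c; the proposal is clamped and accepted only on improvement.
   The heavy tails produce occasional long jumps that escape local optima;
   the zero vector is a fixed point of the update.
3. **Longitudinal–lateral (crisscross) crossover.** Shuffled pairs (i, j)
   produce per-dimension offspring `r·x_i + (1−r)·x_j + c·(x_i − x_j)`
   with `r ~ U(0,1)`, `c ~ U(−1,1)` (horizontal, probability 1.0); single
   individuals mix two of their own dimensions
   `x[d1] ← r·x[d1] + (1−r)·x[d2]` (vertical, probability 0.6). Offspring
   replace parents only on improvement, preserving elitism.

A single seeded generator (`numpy.random.default_rng(seed)`) drives a run
end to end — chaotic seed, migration draws, mutation, crossover — so a
(config, variant, seed) triple reproduces a trace bit for bit.

### Benchmark suite

The 23 classical functions (unimodal F1–F7 at dimension 30, multimodal
F8–F13 at dimension 30, fixed-dimension F14–F23) with their canonical
bounds and published minima. The noisy Quartic (F7) takes an explicit
generator for its additive U[0,1) term so runs stay reproducible; without
one it evaluates its deterministic part. Optimum positions for the
tabulated-coefficient functions (Foxholes, Kowalik, Hartmann, Shekel) were
refined numerically to ~1e−10 so the registry's self-checks can use tight
tolerances. The headline comparison (population 30, 500 iterations,
10 seeds per variant per function) takes about a minute on one core
because objectives evaluate whole populations as matrices.

## The wrapper (FSRML)

ISTOA searches continuous positions of dimension 33 in `[−4, 4]`. Each
evaluation binarises the position with the sigmoid transfer
`bit = 1 ⟺ S(x) > 0.5 ⟺ x > 0`; an all-zero mask is repaired by forcing
the bit with the largest transfer value (the empty subset is infeasible).
The objective is `1 − mean stratified 5-fold accuracy` of the base
classifier fitted on the retained columns; fold assignment depends only on
(cohort, folds, seed), so the objective is a deterministic function of the
mask and results are memoised by mask. No feature-count penalty is applied:
accuracy alone is the stated objective of the framework.

Base classifiers: logistic regression, decision tree, k-nearest
neighbours, a single-hidden-layer feed-forward network, an RBF support
vector machine, random forest, and XGBoost — all with library defaults and
fixed seeds; scale-sensitive learners run behind a standardising pipeline.
The default search budget for cohort-scale problems is population 16,
30 iterations: classifier fits dominate the cost and the memoised mask
space saturates quickly at this dimension.

Evaluation reports pool the out-of-fold predictions into a single confusion
matrix (PR-AUC of small individual folds is unstable), compute threshold
metrics at probability 0.5, the trapezoidal ROC-AUC, and the step-wise
(non-interpolated) PR-AUC. The wrapper objective itself uses mean-of-fold
accuracy; with equal fold sizes the two conventions coincide.

## Statistics

Univariate screening compares the nodule-negative and -positive groups
feature by feature: Pearson chi-square without continuity correction for
binary predictors, pooled-variance two-sample t for continuous ones. The
no-correction chi-square and the pooled (not Welch) t are deliberate: they
are the conventions under which the published statistics of the reference
cohort reproduce exactly to three decimals from its printed counts and
(mean ± sd, n) summaries, and both alternatives are available as options.

The multivariable step is a forward-stepwise logistic regression: the
candidate with the smallest likelihood-ratio p enters while below 0.05,
followed by backward removal of terms whose Wald p exceeds 0.10 (the
conventional stepwise thresholds of mainstream statistical software).
Maximum-likelihood fits use Newton/IRLS via statsmodels. The final table
reports β, SE, Wald = (β/SE)², p, EXP(B) = e^β and the log-symmetric
95% CI `e^{β ± 1.96·SE}` — the standard form for logistic models;
arithmetically symmetric CIs around the odds ratio, which sometimes appear
in print, are not emitted.

## Synthetic cohorts

No subject-level data are distributable, so the generator emulates the
reference cohort: n = 4,861, positive prevalence 1168/4861 ≈ 0.2403, and a
33-predictor schema (12 general/lifestyle, 21 laboratory). Eight
predictors — age, smoking or frequent passive smoking, psychological
stress, occupational exposure, chronic lung disease, family history of
lung cancer, serum albumin, elevated CEA — carry class contrasts calibrated
to the cohort's published class-conditional summaries (e.g. smoking 39.78%
in negatives vs 69.78% in positives; age 33.87 ± 8.43 vs 43.32 ± 9.16
years). The remaining 25 predictors take placeholder marginals at standard
adult reference values, identical in both classes, and therefore act as
pure noise; they are flagged `calibrated: false` in the schema.

One schema reconciliation was needed: the source feature list omits
occupational exposure even though it is one of the eight selected risk
factors, while listing the albumin–globulin ratio, a deterministic function
of two other columns. The schema keeps 33 predictors by including
occupational exposure and dropping the ratio.

Two generators serve different test surfaces:

- **Class-conditional** (`generate`): label first, then features given the
  class — contrasts hold in expectation, the right null/alternative
  structure for testing the univariate statistics.
- **Logistic-link** (`generate_logistic`): features from pooled mixture
  marginals, labels Bernoulli(σ(β₀ + β·x)) with continuous predictors
  z-scored and binary predictors raw 0/1 in the linear predictor. The six
  published multivariable coefficients are used verbatim as generating
  effects; family history (0.7) and albumin (−0.45), retained univariately
  but absent from the published multivariable model, carry documented
  placeholder effects. The intercept is calibrated by bisection to hit the
  target prevalence, and all generating values are recorded in the
  cohort's metadata as ground truth.

Features are drawn independently (no covariance information is available
for the reference cohort); real laboratory panels are correlated, so
passing tests demonstrate recovery under independence, not robustness to
collinearity. Continuous features are Gaussian; real distributions (CEA,
triglycerides) are skewed. Missingness is not modelled.

## Calibration experiments and problem sizes

- **Variant comparison:** full 23-function suite, population 30,
  500 iterations, seeds 0–9 per variant; ISTOA's median final best is at
  least as good as STOA's on 21 of 23 functions in the reference run.
- **Type-I error:** 200 class-conditional cohorts of n = 1,000; the
  univariate screen flags pure-noise predictors at ~5% (5.3% in the
  reference run), matching the nominal level.
- **Parameter recovery:** 10 replicate logistic cohorts of n = 5,000; the
  mean stepwise estimate of each generating coefficient lies within ±0.15
  of truth. Replication matters: a single draw carries SE ≈ 0.2 on the
  rare-binary coefficients (elevated CEA has ~2.4% pooled prevalence), so
  recovery is a statement about bias, not about any one sample.
- **Feature recovery:** five seeded wrapper fits on a logistic cohort of
  n = 1,000. Informative features are selected more often than noise
  features *on average* (0.80 vs 0.68 mean frequency in the reference
  run), but the strict every-informative-above-every-noise ordering is not
  attainable at this sample size with an accuracy-only objective: the
  fold-level noise of cross-validated accuracy (±0.006) exceeds the
  marginal accuracy signal of the weakest effects (albumin at −0.45 per SD
  contributes ~0.005), and adding a pure-noise column *improves* the
  fold-fixed CV objective for roughly half the noise columns. This is an
  identifiability limit of accuracy-driven wrapper selection at n = 1,000,
  and it is reported as such rather than patched with a sparsity penalty.

## Known limitations

- The base STOA is origin-biased by construction; benchmark conclusions
  transfer only qualitatively to search spaces whose optima are far from
  the centre. The wrapper's search box is symmetric about zero, where this
  bias is harmless (it shrinks positions, not masks).
- Base classifiers use library defaults; no hyperparameter tuning.
- Stepwise selection inherits the usual post-selection inference caveats:
  reported p-values are conditional on the selected model.
- The synthetic generator reproduces marginal contrasts, not joint
  structure; conclusions about correlated real cohorts require external
  validation.
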