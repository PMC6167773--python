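# Methods

## Scoring model

The battery aggregates 25 component point values into four domains and
an overall score.  Each domain `D` has components with maxima summing
to `raw_max(D)` and a divisor (5 for Physical Competence, 1 otherwise),
so the domain maxima are 32 / 32 / 18 / 18 and the overall maximum is
100.  Components are treated as continuous on `[0, max]` — published
cohort tables show fractional means for nominally 1-point items, so no
integrality is assumed.

Missing-data allowances:

* **One missing component** in a domain (allowance on): the present
  component sum `s` with present maximum `p` is re-weighted to
  `s · raw_max / p` before the divisor.  Two or more missing
  components make the domain score missing.
* **One missing domain**: the present domain sum is re-weighted to 100
  by `s · 100 / (100 − missing domain max)`.  Two or more missing
  domains make the overall score missing.

The allowances stack: a child may have one missing component in each of
several domains *plus* one wholly missing domain and still receive an
overall score.  Whether the original instrument intended simultaneous
component-level allowances across domains is not documented anywhere we
know of; stacking is this package's choice, motivated by the observation
that in practice the overall score is missing far less often than the
union of component missingness would imply.  A switch
(`db_reweight=False`, CLI `--no-db-reweight`) suspends the allowance
for Daily Behaviour only, since a missing pedometer component is by far
the largest single source of missing data and re-weighting it from the
two self-report components is the most aggressive extrapolation in the
battery.

## Synthetic cohort generator

`generate_cohort` emulates an 11-site cross-sectional study of children
aged 8–12 (uniform age, binary gender, grade = floor(age) − 5 with
±1 classroom noise).  Two standard-normal latent factors with
correlation 0.6 drive the covariance structure: *fitness* loads on the
seven Physical Competence protocols and *activity* on daily steps
(2,200 steps per SD around a 10,000-step mean), MVPA days (positively)
and screen hours (negatively).  Questionnaire domains are generated at
the component level on a 0–10 scale (no item level), loading on
knowledge/motivation latents correlated 0.3 / 0.5 with activity.
Per-component target means are calibrated so the shipped scoring bands
produce point distributions comparable to published cohort summaries
(e.g. steps ≈ 10/21, screen ≈ 5/8, MVPA ≈ 2.2/3).

Site weights are 0.16/3 for three "high" sites, 0.28/4 for four "mid"
sites and 0.56/4 for four "low" sites.  Sites carry activity offsets
(+0.6 / +0.1 / −0.35 SD by group), so site membership predicts both
activity level and (under the default mechanism) pedometer missingness.

### Missingness mechanisms

`apply_missingness` supports per-variable MCAR(rate), MAR (per-group
rates keyed by a fully observed driver) and MNAR (logistic in the
variable's own standardised value), with joint masking for variable
groups, and returns a truth mask so parameter recovery can be measured.
The shipped default assigns MCAR rates of 1.0–6.4% to age and the
protocol variables, masks the two screen-time items jointly at 2.6%,
and masks all 14 pedometer day-level variables jointly by site at
69.2% / 38.2% / 21.4% (high/mid/low).  With the default site weights
this combines to ≈ 33.8% missing steps overall
(0.692·0.16 + 0.382·0.28 + 0.214·0.56 = 0.3375).

Because the high-missingness sites are also the most active, observed
pedometer data under-represent active children: complete-case step
summaries are biased and the direction of the imputed-vs-original
Daily Behaviour contrast (imputed lower) emerges mechanically — the
re-weighted DB score extrapolates from screen/MVPA components that
score a higher fraction of their maxima than steps do.

What the generator does **not** emulate: realistic anthropometric
reference curves, item-level questionnaires (components are generated
directly), day-of-week step structure, accelerometry, or attrition over
the week.  Tests passing on this cohort therefore certify the
*machinery* (scoring, diagnostics, tree, imputation, contrasts) under a
controlled MAR mechanism, not the behaviour of any real cohort.

### Stand-in scoring table

Real raw-score→points lookup tables live in the battery manual and are
not reproduced.  The shipped table (`data/scoring_table.json`, labelled
synthetic) maps each raw variable to points by a monotone
piecewise-linear band from a zero-point anchor to a full-point anchor,
optionally gender-adjusted (PACER, grip); `hi < lo` encodes
less-is-better components (waist, screen time), and the BMI-z component
scores distance from zero.  The pedometer component uses a valid-day
rule: a day counts if wear time ≥ 10 h; at least 3 valid days are
required, else the component is missing; the mean over valid days is
banded from 2,000 to 18,000 steps.  All three thresholds are
configuration, not claims about the official instrument.

## Missingness diagnostics

Per-variable missing proportions (full precision internally, 1-decimal
percent in the report view), unique missing/present pattern tables
(sorted by count descending, then lexicographically — a fixed order
chosen for reproducible reports) and complete-case counts.  The
complete-case count always equals the all-present pattern's count.

## Recursive partitioning of missingness

A from-scratch binary CART models a missingness indicator on
demographics (age, gender, height, weight, grade, site).  Numeric
predictors are scanned exhaustively over midpoints; categorical
predictors are ordered by event rate and scanned over contiguous
prefixes, which attains the optimal binary-outcome subset split without
2^k enumeration.  Ties break by predictor column order then lowest
threshold, making the tree a pure function of the data; rows with
missing predictors are dropped with a logged count.

Stopping rules: `max_depth=4`, `min_leaf=20`, and a complexity
parameter `cp=0.01` requiring a split's n-weighted impurity decrease to
be at least 1% of the root node's total impurity (the rpart
convention).  The relative criterion is the operative one: an absolute
decrease floor alone (the `min_decrease=1e-4` numerical guard) would
accept chance splits on pure-noise indicators at realistic sample
sizes, where the best spurious decrease scales like 1/n.  No pruning or
cross-validation is performed; the intended use is descriptive (which
observed covariate best predicts missingness — a missing-at-random
screen), not prediction.

## Chained-equation imputation

`mice` runs m independent chains (seeded `seed + chain`).  Each chain
initialises every missing cell with a uniform draw from the variable's
observed values, then sweeps the imputed variables in fixed
left-to-right column order for the configured iterations (defaults
m=5, 50 iterations, matching common practice for exploratory MI).

* **Continuous — predictive mean matching** (donor pool k=5, the mice
  default).  A linear model is fitted to the observed rows; the
  residual variance is drawn as RSS/χ²(n−p) and the coefficients from
  N(β̂, σ²(XᵀX)⁻¹) — a proper-imputation posterior draw.  Observed-row
  predictions use β̂ and missing-row predictions use the draw (type-1
  matching); each missing row receives the observed value of a donor
  chosen uniformly among the k nearest predictions.  Imputed values
  therefore always lie in the observed support.  Singular designs fall
  back to a ridge (λ=1e−6) fit with a logged warning.
* **Ordered categorical — proportional odds** (cumulative logit
  P(y ≤ j|x) = σ(α_j − xβ)) and **unordered categorical — polytomous
  logistic**, both fit by Newton–Raphson (max 50 iterations, tolerance
  1e−8, step-halving; the Hessian is a forward-difference Jacobian of
  the analytic gradient).  Coefficients are drawn from
  N(θ̂, I(θ̂)⁻¹) and categories sampled from the fitted probabilities.
  Separation or a singular information matrix triggers a fallback to
  PMM on integer category codes, clamped to the observed categories,
  with a logged warning.

The default model assignment treats measurements and counts as
continuous (PMM), MVPA days and school grade as ordered categorical,
and site/gender as unordered categorical.  Day-level pedometer
variables are imputed individually and the steps component re-scored
from the completed days.  Predictor sets default to all other imputed
variables plus site, age and gender; an incomplete demographic
predictor (age, 1% MCAR) is automatically added to the imputed set so
designs stay complete.  Observed cells are never altered (asserted
cell-exactly in tests), and per-chain traces of imputed-value means/SDs
support convergence checks.

## Contrast statistics

Cohen's d uses the pooled-SD convention
`d = (m₁−m₂)/√(((n₁−1)s₁²+(n₂−1)s₂²)/(n₁+n₂−2))`; the convention was
certified by recovering published 2-decimal effect sizes from printed
(n, mean, SD) triplets.  Group summaries report per-variable n/mean/SD
by a binary grouping (e.g. steps missing vs not), excluding rows where
the variable itself is missing.

The imputation contrast stacks the original scored dataset with the m
re-scored imputed datasets under a dataset indicator 0..m (0 =
original, the reference) and fits OLS of each domain score on the
indicator dummies; rows with a missing score are dropped (counts are
retained for audit).  p-values use the t distribution with n−p degrees
of freedom, unadjusted, and plain (non-robust, non-clustered) standard
errors — the simplest defensible choice for a descriptive contrast.
Rubin's-rules variance pooling is deliberately out of scope: the
comparison of interest is between datasets, not a pooled estimate.

## Problem sizes and reproducibility

Every stochastic step takes an explicit integer seed and is
deterministic given it.  The test suite exercises the stochastic
properties at cohort sizes of 800–10,000 with 20-seed replication for
majority properties (tree root-split selection, MICE bias reduction,
contrast direction) and m=5 chains with 4–10 iterations on the toy and
reduced-pipeline checks — sizes chosen so the full suite completes in
a couple of minutes while leaving the binomial error bands far smaller
than the effects being detected.  `scripts/acceptance.py` is
desk-scale: it recomputes single-child scoring quantities exactly.

## Known limitations

* The stand-in scoring bands are linear; real battery tables are
  age/gender-specific step functions.  Point distributions are
  calibrated at the mean, not across the full shape.
* Proportional-odds/polytomous fits use a numerical Hessian; for very
  wide designs an analytic Hessian would be faster.
* The tree has no surrogate splits, so rows with missing predictors are
  dropped rather than routed.
* `run_pipeline` with all ~40 raw variables, n=10,000, m=5 and 50
  iterations is a long-running job; restrict `impute_variables` (as in
  the README example) for interactive use.
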