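# Methods

## The estimand and the modelling chain

The analysis targets the association between cumulative early-life adversity
and a combined midlife outcome — multiple long-term conditions (MLTCs, ≥ 2 of
22 self-reported conditions) together with SF-36 role limitation — and the
counterfactual question of how much of that outcome could be removed by
reducing adversity. The chain is:

adversity scores → multiple imputation → nested logistic models → scenario
PAFs by model-based standardisation → counterfactual intervention rollout and
absolute-risk-reduction projection.

### Adversity scores

Each early-life variable becomes a binary indicator (1 = adversity). Variables
with accepted cut-offs use them: birthweight uses the WHO low-birthweight
convention of 2500 g (strictly below), and the Rutter behaviour screen is
generated directly as its high-risk class. Variables without an accepted
cut-off are flagged at the **bottom decile** of the cohort distribution. The
percentile convention is fixed deliberately: the type-7 (linear-interpolation)
sample percentile with a *strict* comparison, so ties at the cut-off are never
adverse. Percentile dialects change flag counts, and this choice makes them
reproducible. Indicators are summed per domain without weights — each variable
is assumed to carry an equal relationship to the outcome — and capped at "3+"
because cells with four or more adversities are sparse. Capping is idempotent.

### Outcome

Each SF-36 role-limitation scale is the mean of the *answered* binary items
(4 physical, 3 emotional); a scale score of exactly 0 flags limitation, and a
scale with every item missing is missing. Cases report MLTCs and limitation;
controls report neither; participants with exactly one component
(role limitation only, or MLTCs only) are excluded so that the control group
is free of both. A long-term-condition count that could still reach 2 once
missing flags are known (e.g. one "yes" plus a missing flag) leaves the group
undetermined rather than guessing.

### Multiple imputation

Chained equations over the analysis view (raw early-life variables, sex,
ethnicity, adult covariates, the case indicator). Conditional models are
matched to variable type: Bayesian-draw linear regression for continuous
variables, Bayesian-draw logistic regression for binaries, a linear model
snapped to the nearest observed level for ordered categorical codes, and a
log-scale linear model for weekly income (a plain linear draw can produce
negative incomes, which the analysis log-transform cannot accept). Posterior
parameter draws — β* ~ N(β̂, Σ̂), and for linear models σ²* from the scaled
inverse-χ² — make the M completed datasets genuinely differ, which is what
Rubin's between-imputation variance measures. Predictive-mean matching is not
implemented. A conditional logistic fit that separates or fails to converge is
refitted with a small L2 penalty (λ = 0.5) and logged.

Defaults: **M = 50** imputed datasets and **10 cycles** per dataset. The
outcome takes part in every conditional model, but rows whose outcome was
originally missing are deleted from the analysis tables afterwards
(multiple-imputation-then-deletion), so imputed outcome values are never
analysed. Observed cells are preserved bit-exactly across all M copies.

Pooling is always on the coefficient scale (log-odds, log-PUF), never on the
OR/PAF scale: pooled estimate = mean, T = W + (1 + 1/M)B, t reference with
ν = (M−1)(1 + W/((1+1/M)B))², normal reference when B = 0.

### Logistic estimation

Maximum likelihood by iteratively reweighted least squares (Fisher scoring)
with step-halving, so the log-likelihood is non-decreasing; convergence is a
relative log-likelihood change below 1e−10 within 100 iterations; Wald
covariance is the inverse information at the optimum. A coefficient wandering
past |β| > 15 in an unpenalised fit is reported as perfect separation rather
than returned. The estimator is cross-checked in the test suite against
statsmodels and against direct numerical maximisation of the likelihood.

Model levels: (1) one domain's score dummies + sex + ethnicity, fitted per
domain; (2) all five domains jointly + sex + ethnicity; (3) level 2 plus adult
factors. Ordered adult covariates (exercise days, TV and internet hours, IMD
decile, financial difficulty, education, occupational class, alcohol class)
enter linearly in their level codes — full dummy expansion would cost ~40
extra parameters and destabilise small synthetic fits; weekly income is
log-transformed and standardised. Ethnicity is binary in the generator (the
emulated cohort is overwhelmingly of one ethnic group), so a single dummy
suffices. If a score category is empty in any completed dataset it is merged
upward (1 → 2 → 3+) with a logged warning so the dummy design stays full rank.
Significance is a per-cell 95% interval; no multiplicity adjustment, matching
how such tables are conventionally read.

### Scenario PAFs

For a scenario a→b within a domain, restrict to analysed participants with
score category a; p_factual is the mean model-3 predicted probability at their
observed covariates, p_counterfactual the mean prediction with that domain's
dummies switched to b and everything else fixed. PUF = p_cf / p_f,
PAF = 1 − PUF. The reference population is therefore the exposed subgroup
itself, matching the regression's reference coding. Two uncertainty routes:

* **bootstrap** (default): 200 seeded nonparametric resamples of the analysis
  table, refit, recompute log PUF; the resample variance feeds Rubin pooling
  within each imputed dataset. Unstable resamples (empty exposed group,
  singular fit) are skipped; fewer than 10 usable draws is an error.
* **delta**: the gradient of log PUF with respect to β against the Wald
  covariance. Used where speed matters and in the calibration tests.

Bootstrapping inside each imputed dataset and then Rubin-pooling is one
defensible ordering among several; it keeps the bootstrap conditional on the
imputation draw. PAF grids are restricted to domains significant in model 3
(any score category), with an explicit override for calibration studies.

### Counterfactual rollout and projection

The intervention library holds eleven published effects: birthweight +324 g
for everyone (additive); and fractions of the at-risk group reclassified to
non-adverse — smoking in pregnancy 8%, teenage pregnancy 62%, Rutter high-risk
39%, behavioural problems 55%, temper 2.6%, and 6% for each of five
developmental markers (walking backwards, hand control, clumsiness, right/left
balance). No intervention targets maternal age or parity. Reclassification
samples round(f · n_eligible) participants without replacement
(half-away-from-zero rounding); effects are variable-disjoint and each draws
from a sub-seed derived from its target variable, so library order cannot
change the result — permutation invariance is asserted.

Interventions are applied to each completed dataset (universal rollout),
scores are recomputed, and category transitions are counted among cases only;
indicators are only ever reduced, so a score that increases is a hard error.
Mover counts are averaged over the M datasets (they may therefore be
fractional); whether to count movers per dataset or once on a pooled dataset
is genuinely open, and averaging uses all M rollouts without inventing a
pooled cohort.

Projection applies the scenario PAF to the movers. Because published
projections round inconsistently, **both conventions are first-class**:
fractional (PAF × movers, ARR = 100 · PAF · movers / group cases) and integer
(nearest whole person first). They bracket each other within
100/group_cases percentage points and neither is silently preferred.

## The synthetic cohort generator

The generator emulates the *structure* of a 1970s British birth cohort
followed to age 46: n = 8580 by default (the pre-exclusion denominator of the
emulated study), five adversity domains with 5/8/4/4/4 variables, 22
long-term-condition flags, 7 SF-36 items, and twelve adult covariates.

* **Dependence.** One standard-normal latent factor per domain (loading 0.5)
  plus one global factor across domains (loading 0.3). Within-domain
  correlation keeps 3+ cells populated — independent indicators would make
  them vanishingly rare — and cross-domain correlation is what lets the
  mutual-adjustment model (level 2) attenuate the single-domain model, as the
  joint analysis of correlated life-course domains requires.
* **Continuous variables** are limited to birthweight
  (Normal(3350 g, 500 g) truncated at 500 g) and one raw score per
  motor/ability variable (standard normal, adversity = low tail), so the
  bottom-decile rule has something to act on; all other indicators are drawn
  directly as binaries with marginal prevalences in [0.05, 0.30]. Those
  prevalences are plausible placeholders, not estimates of the emulated
  cohort.
* **Outcome.** The case indicator follows a declared logistic model on the
  capped domain scores (log-odds 0.18–0.35 per score point), sex and adult
  covariates. The intercept is calibrated at generation time (root-finding on
  the mean predicted risk) so analytical-sample case prevalence sits near
  11.9%. Exclusion statuses (MLTCs-only 24%, role-limitation-only 3.8%) are
  drawn independently of covariates; condition flags and SF-36 items are then
  generated *consistent with* the assigned group, so deriving the outcome from
  the generated table reproduces the latent truth exactly.
* **Mediation.** Adult covariates depend on the total adversity score
  (cumulative log-odds shift ±0.3 per point, smaller for weakly related
  covariates) and carry their own outcome coefficients, so the fully adjusted
  model attenuates the early-life ORs — the generator encodes the mediation
  narrative the model levels are designed to reveal.
* **Missingness** is missing-at-random by construction: each variable's
  missingness probability depends only on sex and one always-observed
  adversity indicator (log-odds shifts 0.4 and 0.3), with the intercept solved
  to hit the target marginal rate (5–12% by default). Setting the shifts to
  zero gives MCAR.

What the generator does **not** emulate: the real sampling design and
attrition, 1970s measurement instruments, nonlinear or interactive effects,
informative (MNAR) missingness, and any correlation between intervention
uptake and circumstances. Passing tests therefore demonstrate that the
pipeline's machinery is correct and calibrated under its stated assumptions —
not that the emulated study's substantive estimates are right.

## Problem sizes used in tests and the acceptance script

Statistical properties are checked at sizes chosen to make the checks sharp
yet quick: ground-truth coefficient recovery uses 50 complete cohorts of
n = 20 000; null calibration of PAF intervals uses 40 replicates of n = 4000
with M = 2 and 5 cycles; MCAR coverage uses 40 replicates of n = 2500 with
M = 5; attenuation uses 25 cohorts of n = 4000; PAF monotonicity uses
cohort-scale n = 8580, where per-category dummy estimates are stable. The
acceptance script runs the full chain once at n = 8580 with M = 3, 5 cycles
and delta-method PAF intervals. These are run-size choices of this package;
the statistical conclusions do not hinge on them.

## Known limitations

* Ordered covariates imputed as rounded linear draws are coarse; no
  predictive-mean matching.
* The bootstrap/imputation ordering (bootstrap within imputation) understates
  imputation uncertainty slightly relative to bootstrapping the whole chain.
* Single-dataset `paf_scenario` intervals use the delta method; bootstrap
  intervals are available only through the grid function, which owns the
  refitting loop.
* Intervention effects are assumed additive and independent across the
  library; uptake is random within the at-risk group by design, not a model
  of real-world uptake.
* PAF estimates apply to the exposed subgroups of the analytical sample, not
  to a general population.
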