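# Methods

## Scientific setting

Vaginal fistula (VF) symptoms are ascertained in DHS/MICS-style household
surveys by asking women aged 15–49 whether they have ever experienced
uncontrollable leakage of urine or stool from the vagina. The outcome is
rare (a few reports per 1,000 women) and the question is asked only of
eligible subgroups in some surveys (ever-married, ever-pregnant, or
recently delivered women). Pooling surveys is unavoidable: at the level of
a single survey most cells of the exposure × outcome table are empty.

The analysis estimates the association between candidate risk factors
(literacy, education, FGM, short stature, intimate partner sexual
violence, young age at first sex, young age at first birth, difficulty
obtaining permission to seek care) and lifetime VF symptoms, combining
three layers of defence against bias:

1. **harmonization** — per-factor eligibility and common exposure coding
   across surveys;
2. **matching** — k:1 nearest-neighbour preprocessing so exposed and
   unexposed groups overlap on sampling weight, age and survey;
3. **misclassification-adjusted regression** — a latent-class Bayesian
   grouped-binomial logistic model linking the self-report to the latent
   true status through sensitivity and specificity.

Steps 2 + 3 together form a doubly-robust design: inference is consistent
if either the matching or the outcome regression is correctly specified.

## Outcome model

For covariate pattern *i* with `N_i` women and `y_i` positive reports:

    y_i ~ Binomial(N_i, p_i)
    p_i = π_i·Se + (1 − π_i)·(1 − Sp)
    logit(π_i) = α + β·x_i

Grouping by covariate pattern makes the likelihood cost independent of the
number of women (hundreds of thousands of rows collapse to ≲100 groups)
and is exactly equivalent to the row-wise Bernoulli model (tested to
1e-8). `p_i` always lies in the envelope `[1 − Sp, Se]` and is increasing
in `π_i` whenever `Se + Sp > 1`.

Why the adjustment matters: with true prevalence π ≈ 0.002, Sp = 0.999 and
Se = 0.975, the reported cases are roughly one-third false positives
(apparent prevalence 0.002461 vs 0.00195 true positives). False positives
are spread across exposure groups in proportion to group size, so the
naive odds ratio is pulled toward 1. In the package's replicated
simulations with a true OR of 2 the naive posterior median is ≈1.7 while
the adjusted model re-covers 2 (see `scripts/acceptance.py` output).

### Priors

* `α, β ~ Normal(0, sd = 20)` — effectively flat on the log-odds scale;
  the SD is a standard deviation, not a variance.
* `Se ~ Uniform(0.9510, 0.9990)`, `Sp ~ Uniform(0.9985, 0.9995)` — the
  95% credible ranges of a prior validation of fistula self-report
  against pelvic examination; Se/Sp are treated as common to all surveys
  and are not estimable from the survey data themselves, so the posterior
  for them stays close to the prior. Degenerate bounds `(1, 1)` fix the
  parameter and reduce the model to ordinary logistic regression
  (`PriorSpec.perfect_test()`).

### Identification and the role of the prior

With no internal validation data, (α, Se, Sp) are jointly identified only
through the informative uniform supports. The credible interval for an
exposure OR under the adjusted model is therefore wider than the naive
interval: it propagates the uncertainty about how many reported cases are
real. This is a feature, not a convergence problem.

### Sampling

Posteriors are sampled on an unconstrained scale: coefficients as-is, and
`Se`, `Sp` through a scaled logit onto their uniform supports (with the
log-Jacobian `log s(u)(1−s(u))` absorbed into the target). The sampler is
a random-walk Metropolis with:

* initialisation at the posterior mode (L-BFGS with analytic gradients);
* proposal covariance from the Laplace approximation at the mode
  (finite-difference Hessian of the gradient, eigenvalue-floored, with
  per-axis SD capped at 5 so weakly identified Se/Sp directions do not
  dominate), scaled by `2.38/√d`;
* warm-up with batched Robbins–Monro adaptation of the global scale
  toward acceptance 0.234, frozen before the retained draws.

The posterior, not the sampler, is the contract: for this low-dimensional
(<~30 parameters), near-Gaussian target the adaptive Metropolis chains
satisfy the same diagnostics a gradient-based sampler would. Two presets
are provided: `McmcConfig.full()` (3 chains × 30,000 retained
after 2,500 warm-up) and `McmcConfig.test()` (3 × 1,000 after 1,000),
which is amply precise for the simulation studies and keeps each fit
under ~1 s. Convergence is assessed with the split-chain potential scale
reduction factor; the implementation floors the raw statistic at 1.0 so
that 1.0 always reads "converged", returns +inf for constant-but-unequal
chains, and is cross-checked against ArviZ in the tests. Effective sample
size is delegated to ArviZ. Draws are persisted as `.npz` named arrays
(chain × draw) rather than netCDF; the format is self-describing via
parameter names and loads with `numpy` alone.

### Reporting

Point estimate = posterior median (invariant under the exp transform, so
summarising β then exponentiating equals exponentiating then summarising);
interval = equal-tailed 2.5th/97.5th percentiles of the OR draws;
significance = the 95% CrI excluding 1; percent change in odds
`(1 − OR)·100` reported alongside. Display rounding is two decimals.

For literacy and education, gravidity plausibly lies on the causal path
(literate women have fewer pregnancies, and gravidity raises fistula
risk), so `direct_vs_total` fits the model twice on the same matched
table — with gravidity (direct effect) and without (total effect). The
contrast is restricted to those two factors; age at first birth excludes
gravidity from adjustment outright.

## Harmonization rules

* **Literacy**: literate iff the full test sentence was read, or some
  secondary schooling is reported (de-facto literate); partial reading
  codes as not literate; with neither field, missing.
* **Dichotomizations** (strict inequalities, exposure = below threshold):
  height < 150 cm; age at first sex < 14 years; age at first birth < 14
  years; "big problem" obtaining permission to seek care.
* **Inconsistent responses**: "never had intercourse" with a birth on
  record makes age at first sex missing; a consistent "never" keeps the
  woman out of the sexually-active denominator rather than counting as
  missing data.
* **Survey-level defaults**: surveys without gravidity impute it from
  parity (every nulliparous woman assumed nulligravid); surveys without
  religion carry an explicit missing category, which is retained as its
  own level in the regression rather than triggering row deletion.
* **Complete-case analysis**: any other missing exposure, covariate,
  outcome or weight drops the row (missingness in these surveys is ≲1–2%
  per field and is simulated as MCAR, under which complete-case logistic
  regression is unbiased).
* **Adjustment covariates**: age binned 15–19 / 20–29 / 30–49 (age at
  interview — the only age the surveys carry — is matched on continuously
  and then binned for regression), literacy (except for the two
  literacy/education factors), gravidity (except for age at first birth),
  urban residence, religion, and country fixed effects (disabled for age
  at first birth and permission-to-seek-care). Reference categories are
  fixed: age 30–49, christian, and False for booleans.

## Matching

Greedy sequential k:1 nearest-neighbour matching without replacement:

* distance: Euclidean on (sampling weight, age), standardized against the
  pre-match table (so before/after balance shares a scale); the
  domestic-violence module weight replaces the household weight for IPSV;
* exposed units processed in seed-shuffled order; candidate ties broken
  by row order;
* survey identifier: an exact constraint for the consistently rare
  exposures (short stature, IPSV, young first sex, young first birth,
  permission), otherwise a same-survey preference implemented as a large
  additive penalty (1e6) on cross-survey distances — same-survey controls
  always win, but an exposed woman whose survey has run out of controls
  can still be matched rather than discarded;
* matching ratios per factor: 1:1 (literacy, education, FGM, permission),
  1:2 (IPSV), 1:3 (young first sex), 1:4 (short stature), 1:8 (young
  first birth);
* exposed units with some but fewer than k controls are retained with a
  warning (cases are too rare to discard); exposed units with zero
  eligible controls are dropped with a logged count.

Balance is summarised as standardized mean differences using the
pre-match pooled SD. Matching reliably improves age balance when controls
are in adequate supply — the situation of the high-ratio factors here,
which are all rare exposures; with near-balanced exposure and high k the
pool can be exhausted and residual imbalance remains (the regression
adjustment is the second line of defence).

## Synthetic-data generator

The generator emulates the pooled-survey structure end to end: 24 surveys
(configurable 20–30) × 12,000 women; log-normal sampling weights
(log-scale SD 0.3) mean-normalised within survey; a decreasing 15–49 age
pyramid; literacy linked to residence and age; religion ~55/35/10%
christian/muslim/other; marriage and gravidity increasing with age;
heights N(158, 5.9) giving ~9% short stature; ~11% sexual debut before
14 and ~4–7% first birth before 14 among the eligible; IPSV only among
ever-married women with a perturbed domestic-violence weight; a
configurable focal exposure with mild age/literacy confounding (log-OR
0.3) so matching and adjustment have real work to do; outcome from the
logistic model above (default baseline intercept −6.9, i.e. ~2–3 true
cases per 1,000 marginally; default exposure log-OR log 2) and
non-differential misclassification at Se = 0.975, Sp = 0.999 (the centres
of the prior supports); per-survey outcome eligibility modes; MCAR
missingness (height 2%, age at first sex 4% plus 2% inconsistent
answers, other fields 0.5%).

What it does **not** emulate: country-specific prevalence patterns,
within-survey spatial/cluster correlation of the outcome, MAR/MNAR
missingness, differential misclassification by exposure, or survey-to-
survey variation in Se/Sp. Passing tests therefore demonstrate that the
pipeline recovers known effects under the stated design, not that those
design assumptions hold in any particular real survey.

## Problem sizes and numerical choices

Simulation studies use 20 replicates of 200,000 women (20 surveys ×
10,000) for misclassification recovery, 50,000 for the
reduction-to-logistic oracle, and ~100-group covariate patterns; these
sizes give Monte-Carlo error well below the effects being checked while
keeping a full validation run at a few minutes on one CPU. Likelihood
evaluations clip the apparent probability to [1e-300, 1−1e-16] inside the
sampler for numerical stability, while the public log-likelihood returns
−inf exactly for impossible outcomes (p = 0 with y > 0). A non-full-rank
design raises an error naming the collinear columns before sampling
starts. Degenerate matching inputs (all exposed, all unexposed, empty
tables) raise immediately.

## Known limitations

* Survey-design variance (clustering, stratification) is not modelled;
  weights enter only as a matching variable, mirroring the analysis
  design this package implements.
* Se/Sp are taken as given uniform ranges, not estimated from validation
  data, and are assumed common across surveys and exposure groups.
* Greedy matching is order-dependent (seeded); optimal matching and
  calipers are out of scope.
* The FGM exposure is presence/absence only; cutting extent is not
  distinguishable in these questionnaires.
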