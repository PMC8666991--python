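# Methods

This note documents the models and procedures implemented in `trialcea`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Analytical framework

The package evaluates an intervention against control in a 1:1 randomised
trial over a 12-month horizon, from the UK NHS/personal-social-services
(NHS/PSS) perspective in the base case and a societal perspective
(adding participant out-of-pocket spending on over-the-counter medication,
childcare and travel) as a secondary analysis. Costs are held at 2015
prices; with a one-year horizon no discounting is applied. The base case is
intention-to-treat: participants are analysed as randomised, with missing
data multiply imputed. A complete-case analysis (listwise deletion over the
full economic profile) is the sensitivity analysis, and available-case
(item-wise) summaries serve data exploration.

### Utilities and QALYs

EQ-5D-5L responses map to utilities through a tariff table. The engine is
tariff-agnostic: an exhaustive `state,utility` CSV or an additive
decrement-coefficient CSV both load into the same 3,125-entry lookup, with
two invariants enforced at construction — state 11111 scores exactly 1.0,
and no state exceeds 1.0. Negative utilities are permitted (states worse
than death). A profile with any missing dimension scores as missing; the
instrument has no partial-credit rule.

QALYs are the trapezoid area under the utility curve at the
protocol-scheduled visits (0, 0.5, 1.0 years):
`QALY = 0.25·u₀ + 0.5·u₆ + 0.25·u₁₂`. Actual questionnaire-return dates are
not modelled. Baseline imbalance in utility is corrected by including
baseline utility as a covariate in the estimation model, not by subtracting
it from the area — covariate adjustment is the standard approach and keeps
the QALY itself interpretable.

The shipped default tariff (`data/tariff_synthetic_decrement.csv`) is
**synthetic**: published value sets are licensed and cannot be
redistributed. Its decrements are monotone in severity per dimension, it
carries a severity interaction (an extra decrement once any dimension
reaches level 4–5), and its floor is −0.225. Tests never rely on its
specific values; the documented closed-form linear tariff
(utility = 1 − 0.05·Σ(level − 1)) is the test fixture.

### Costs

Healthcare resource use is costed item-wise as count × unit cost, with the
trial-period total summing the 6- and 12-month questionnaires; the baseline
questionnaire covers pre-randomisation use and enters only as the
baseline-cost covariate. An item-level missing count makes that visit's
resource cost missing (not zero): filling it in is the imputation stage's
decision, and available-case descriptives stay item-wise.

Study-drug cost uses the hydroxychloroquine sulfate 200 mg 60-tablet pack
price (default £5.15): daily cost = (dose/200) × pack price / 60, a 300 mg
dose being alternating 200/400 mg (1.5 tablets/day), multiplied by recorded
treatment days (0–365, truncated at stop/withdrawal). Dose is assumed
constant over the year. Placebo tablets are a research cost and contribute
£0; a control-arm participant with nonzero drug cost is a validation error.

Concomitant medications recorded on investigator forms at 3, 6, 9 and 12
months are costed at category-average prices (oral opioid, oral NSAID,
topical NSAID, antidepressant/neuropathic, other analgesic) rather than
micro-costed per product. The shipped category averages are **uncalibrated
placeholders** (flagged on the `MedicationCategoryCosts` object): the
averages used in any real trial derive from its own prescription records.
Because investigator forms are clinician-completed, the pipeline treats
medication (and drug-exposure) fields as fully observed; missingness
modelling is confined to the self-report questionnaires.

Out-of-pocket expenses are participant-stated £ amounts, so no unit costs
apply; they join the total only under the societal perspective. This can
double-count over-the-counter spending that also appears in the medication
categories; the overlap is documented rather than corrected, as is
conventional when the two sources cannot be linked.

## Missing data

Base-case imputation is MICE with predictive mean matching, applied at the
*component* level — utilities u₀, u₆, u₁₂ and per-visit resource costs (plus
per-visit expense totals under the societal perspective) — and aggregated
into QALYs and totals afterwards. Component-level imputation preserves the
AUC weighting and the costing structure; imputing the aggregates directly
is the cruder alternative and the choice between them is genuinely open in
this design.

Within each chain, continuous variables use a linear model on the
imputation covariates (baseline hand-pain NRS, concomitant analgesic use,
grip strength, BMI, age, gender) plus the current fill-ins of the other
imputable variables; binary variables use a logistic link. Parameter
uncertainty is propagated by drawing coefficients from their estimated
sampling distribution before predicting missing cases; each missing value
is then replaced by the observed value of one of the k nearest donors in
predicted-mean space (type-1 PMM), so every imputation is an actually
observed value. Equidistant donors at the pool boundary are tie-broken
uniformly at random. Defaults m = 20 imputations, 10 cycles, k = 5 donors
follow common practice — none of these is dictated by the method — and are
configuration-exposed. The normal equations carry a 1e-8 ridge so a
near-collinear fill-in cannot abort a chain; non-finite fitted means raise
a divergence error.

Pooling follows Rubin's rules: pooled estimate = mean of per-imputation
estimates; total variance = mean within-imputation variance plus
(1 + 1/m) × between-imputation variance; degrees of freedom by
Barnard–Rubin when a complete-data df is available.

## Estimation

Costs and QALYs are estimated jointly by seemingly-unrelated regression:
each outcome on the arm indicator, baseline utility, baseline cost and the
clinical covariates, estimated by feasible GLS (per-equation OLS → residual
cross-equation covariance → joint GLS). With identical regressor sets the
GLS step reproduces OLS exactly — a classical identity the test suite
checks to 1e-8 — but the joint covariance of (ΔC, ΔE) still requires the
cross-equation correlation. Singular designs raise an error naming the
collinear columns.

Uncertainty propagates by non-parametric bootstrap of whole participants,
stratified by arm so every replicate preserves the 1:1 design. How to
combine bootstrap with multiple imputation is not settled; the default here
is **boot-then-impute** — resample participants, then run a single
stochastic imputation inside each replicate — because it carries imputation
uncertainty into the CE-plane cloud and the CEAC. The alternative
(impute-then-boot: bootstrap within each completed dataset and pool the
clouds) is selectable via `bootstrap_strategy`. Inside bootstrap replicates
the chain runs 5 cycles rather than 10: a resampled dataset starts from the
previous fill pattern's donor pool and converges quickly, and the cloud is
governed by between-replicate variation. B defaults to 5,000 replicates.

Intervals are bias-corrected and accelerated: z₀ = Φ⁻¹(fraction of
replicates strictly below the point estimate), acceleration from the
skewness of leave-one-participant-out jackknife values (not
leave-one-observation-out, since the participant is the resampling unit).
With z₀ = a = 0 BCa reduces exactly to the percentile interval. A fully
degenerate cloud yields the degenerate interval [v, v]; a 95% interval
requires at least 100 replicates.

The pain outcome (hand-pain NRS, 0–10, 6 minus 0 months, negative =
improvement) is analysed on available cases by repeated-measures GLS with
exchangeable (compound-symmetry) covariance: common variance σ² and
within-person correlation ρ, ρ estimated by the method of moments from OLS
residual cross-products and clipped into (−1/(T−1), 1) with a warning if
needed. When the between-arm pain contrast shows no reduction, the
cost-per-pain-reduction ICER is flagged as not meaningful rather than
reported.

## Decision analysis

ICER = ΔC/ΔE carries quadrant semantics: north-east results are cost per
QALY gained; south-east is dominant and north-west dominated (no ratio
reported); a south-west result is reported as a positive cost saved per
QALY lost, and — assuming symmetric preferences over health gains and
losses — is cost-effective only when the saving exceeds the threshold,
which coincides exactly with positive net monetary benefit λ·ΔE − ΔC. "Net
benefit" throughout is the monetary form (units £, matching published
tables); the QALY-denominated form ΔE − ΔC/λ is exposed separately as
`net_health_benefit`.

Boundary conventions are deterministic and conservative: ΔE = 0 or ΔC = 0
counts as gain / cost-increase for quadrant assignment, and a net benefit
of exactly zero counts as *not* cost-effective. The CEAC evaluates the
fraction of replicates with strictly positive net benefit over a λ grid of
£0–50,000 in £500 steps, covering both NICE anchors (£20,000 and £30,000).

## Synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which the pipeline is validated.

* **Design**: 2 × 124 participants (1:1), baseline covariates typical of a
  hand-osteoarthritis population (82% female, age ≈ 62.5 ± 9, BMI ≈ 28,
  baseline pain NRS ≈ 6, two-thirds using analgesics).
* **Utilities**: latent utilities per visit from scaled-beta margins
  (baseline mean 0.61, SD 0.18; +0.025 at follow-up) joined by a Gaussian
  copula (ρ = 0.6), then inverted to the nearest EQ-5D-5L profile under the
  generating tariff. 97% of participants are restricted to
  pain/discomfort ≥ 2, reproducing the near-universal pain problems of this
  population. The configured QALY effect is an additive shift of
  ΔE/0.75 on follow-up latent utilities (follow-up visits carry ¾ of the
  AUC weight); profile discretisation adds snap error far below sampling
  noise at any tested size.
* **Costs**: per item and visit, counts are zero-inflatable gamma–Poisson
  (negative binomial) draws with means matching published availability
  summaries and dispersion 0.8, so SDs exceed means as observed. Drug
  exposure mixes doses 200/300/400 mg at 7:85:32 with 90/124 treated the
  full year (the remainder uniform over 15–308 days), giving an analytic
  mean drug cost ≈ £42.5. Medication-category use rates are calibrated so
  arm mean medication costs hit their configured targets (£282.16 vs
  £300.17). The configured total cost effect is decomposed as drug cost +
  medication contrast + remainder, the remainder applied to the
  intervention arm's hospital-outpatient intensity; an infeasible (negative
  rate) decomposition is a configuration error.
* **Missingness**: masking probabilities depend only on always-observed
  baseline fields through a logistic model (MAR by construction — a
  coefficient on a maskable field is rejected), with per-visit intercepts
  calibrated by root-finding so realised rates match the configured
  marginals (~1% baseline, ~16% at 6 months, ~25% at 12 months). A
  participant missing at 6 months gets a +1.0 logit bump at 12 months (weak
  monotonicity). Instruments within a visit can be coupled through a shared
  Gaussian factor; the default is independence, since the joint pattern
  across instruments is typically unreported.

What the generator does **not** emulate: adverse events, clinical pain
trajectories beyond a configurable mean shift, visit-date jitter,
item-level (as opposed to questionnaire-level) missingness differences, or
any real correlation between resource use and health state. Passing
recovery tests therefore demonstrates that the pipeline is consistent and
correctly propagates uncertainty under MAR — not that it would be unbiased
under the richer dependence structures of real trial data (in particular,
data missing not at random).

## Problem sizes and numerical conventions

Parameter-recovery checks run at 2 × 2,500 participants with m = 20
imputations, where the Monte-Carlo standard errors (≈ £10 for ΔC, ≈ 0.004
for ΔE) are small enough to detect material bias while keeping the full
suite comfortably interactive; interval-coverage checks use 1,000
simulations of an exponential mean at n = 50 with B = 1,000. Worked
decision arithmetic is exact. All stochastic stages draw from
`numpy.random.default_rng` streams derived from one master seed via
`SeedSequence`, recorded in `run.log`; reruns with the same configuration
are byte-identical. Dataset CSVs encode missing values as empty fields;
`gender` is encoded F = 1 in design matrices; ICER and share computations
follow the closed-boundary conventions above.

## Known limitations

* The shipped tariff and medication-category costs are synthetic/placeholder
  inputs; substantive results require the licensed value set and
  trial-specific category averages.
* MNAR sensitivity analysis, multilevel imputation, value-of-information
  analysis and extrapolation beyond 12 months are out of scope.
* The exchangeable-covariance pain model estimates ρ by moments rather than
  ML; for the balanced two-visit design used here the difference is
  negligible.
* Boot-then-impute is computationally dominant (one chained-equation pass
  per replicate); B = 5,000 on a 248-participant trial takes a few minutes
  on one core.
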