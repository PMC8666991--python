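# trialcea

Within-trial cost–utility analysis in Python: from participant-level
EQ-5D-5L responses and healthcare resource-use counts to decision outputs —
incremental costs and QALYs with bias-corrected and accelerated (BCa)
bootstrap intervals, ICERs with cost-effectiveness-plane quadrant semantics,
net monetary benefit, and cost-effectiveness acceptability curves (CEACs).

The package implements the standard pipeline for a two-arm randomised trial
with questionnaire visits at 0, 6 and 12 months, as used in UK health
technology assessment:

* **Utility scoring.** EQ-5D-5L profiles (five dimensions × five levels) are
  mapped to utilities through a pluggable tariff table. Any value set can be
  loaded from CSV, either as an exhaustive 3,125-state table or as additive
  decrement coefficients. A state of full health scores exactly 1; negative
  utilities (states worse than death) are allowed. Published value sets are
  licensed, so the shipped default is a clearly-labelled *synthetic* tariff
  with the qualitative shape of published ones; plug in the licensed tariff
  for your jurisdiction for real analyses.
* **QALYs.** Area under the piecewise-linear utility curve over one year:
  `QALY = ¼·u₀ + ½·u₆ + ¼·u₁₂`. Baseline utility enters downstream as a
  regression covariate, not as a subtraction.
* **Costing.** Resource counts × unit costs (2015 UK £, NHS/PSS
  perspective), study-drug cost from the hydroxychloroquine 200 mg pack
  price (£5.15/60 tablets; 300 mg costed as 1.5 tablets/day) truncated at
  stop/withdrawal, category-average medication costs from investigator
  forms, and participant-stated out-of-pocket expenses under the societal
  perspective. Placebo tablets cost £0.
* **Missing data.** Multiple imputation by chained equations with predictive
  mean matching (MICE-PMM) on cost and utility components, under a
  missing-at-random assumption; Rubin's rules with Barnard–Rubin degrees of
  freedom for pooling.
* **Estimation.** Seemingly-unrelated regression (feasible GLS) of total
  cost and QALYs on the arm indicator and adjustment covariates; the arm
  coefficients are ΔC and ΔE. Non-parametric bootstrap (participants
  resampled stratified by arm, imputation re-run inside each replicate)
  yields the CE-plane cloud; intervals are BCa with leave-one-participant-out
  jackknife acceleration.
* **Decision analysis.** ICER = ΔC/ΔE with quadrant classification (a
  south-west result is reported as positive "cost saved per QALY lost"),
  net monetary benefit λ·ΔE − ΔC at the NICE thresholds £20,000 and £30,000
  per QALY, and the CEAC — the fraction of bootstrap replicates with
  positive net benefit across a threshold grid.
* **Synthetic trials.** Real participant-level trial data of this kind
  cannot be shared, so `trialcea.synthetic` generates two-arm datasets with
  the assumed statistical structure (124 per arm by default, baseline
  utility ≈ 0.61, right-skewed costs, MAR missingness rising to ~25% by 12
  months), with configurable true between-arm effects so every stage is
  testable by parameter recovery.

## Worked example

Simulate a trial at the default study conditions and run the base-case
intention-to-treat analysis (NHS/PSS perspective, MICE-PMM with m = 20,
B = 1,000 bootstrap replicates):

```sh
printf 'n_per_arm: 124\nseed: 7\n' > gen.yaml
printf 'B: 1000\nm: 20\nseed: 7\n' > run.yaml
trialcea simulate --config gen.yaml --out trial.csv
trialcea run --config run.yaml --data trial.csv --out results/
```

which prints

```json
{
  "delta_cost": -26.950974,
  "delta_qaly": -0.00511651,
  "icer": {
    "value": 5267.45,
    "quadrant": "SW",
    "interpretation": "cost saved per QALY lost"
  },
  "net_benefit": {
    "20000": {"value": -75.3792, "ci": [-567.0034, 495.2111]},
    "30000": {"value": -126.5443, "ci": [-859.0057, 717.1506]}
  }
}
```

Reading: on this simulated trial the intervention arm cost £26.95 less per
participant over 12 months and accrued 0.0051 fewer QALYs — the south-west
quadrant — saving £5,267 per QALY forgone. Under symmetric preferences a
saving below the £20,000 threshold does not justify the health loss, so net
monetary benefit is negative (−£75 at £20,000/QALY) and the intervention is
not cost-effective; the wide bootstrap interval shows a single trial of 248
participants leaves that conclusion uncertain. `results/` also contains
`ceac.csv` (probability cost-effective per threshold), `ce_plane.csv` (the
bootstrap cloud with quadrant labels), `availability.csv` (item-wise
missingness descriptives) and `run.log` (all stage seeds).

The same analyses are available directly from Python via
`trialcea.RunConfig` / `trialcea.run_analysis`, and each stage
(`score_state`, `qaly_auc`, `cost_hcq`, `mice_pmm`, `fit_sur`,
`bca_interval`, `icer`, `ceac`, …) is importable on its own.

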