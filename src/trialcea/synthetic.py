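"""Synthetic two-arm trial generator.

The real participant-level dataset behind this kind of within-trial economic
evaluation is individual patient data and cannot be shared, so the package
ships a generator that reproduces the statistical structure the analysis
assumes, making every downstream stage testable end to end:

* 1:1 randomisation of ``2 * n_per_arm`` participants (default 124 per arm);
* baseline covariates typical of a hand-osteoarthritis population (age,
  gender, BMI, hand-pain NRS, grip strength, concomitant analgesic use);
* EQ-5D-5L responses at 0/6/12 months.  A latent utility is drawn from a
  scaled-beta marginal (default mean 0.61, SD 0.18 at baseline, small
  improvement at follow-up) through a Gaussian copula for within-person
  correlation, then inverted to the nearest 5-level profile under the
  generating tariff.  A configurable fraction (default 97%) is restricted to
  pain/discomfort level >= 2, mirroring the near-universal pain problems seen
  in this population;
* right-skewed resource-use counts per item and visit via zero-inflated
  gamma-Poisson (negative binomial) mixtures — SDs exceed means, as observed;
* HCQ exposure (dose mix 200/300/400 mg, most participants treated the full
  365 days), investigator-recorded medication-category uses, and
  out-of-pocket expenses;
* a missing-at-random (MAR) overlay whose masking probability depends only on
  always-observed baseline fields, with rates rising from ~1% at baseline to
  ~25% at 12 months and weakly monotone across visits.

The arm contrasts are calibrated so that complete-data between-arm
differences converge to ``true_delta_cost`` and ``true_delta_qaly`` as n
grows: the QALY effect is an additive shift on follow-up latent utilities
(ΔQALY / 0.75, since follow-up visits carry 3/4 of the AUC weight), and the
cost effect is decomposed into the analytic mean drug cost, the configured
medication-cost contrast, with the remainder applied to the intervention
arm's hospital-outpatient intensity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import schema
from .costing import DrugCostConfig, MedicationCategoryCosts, UnitCostTable
from .eq5d import TariffTable, default_tariff_path, load_tariff, all_states
from .schema import ConfigurationError

__all__ = ["GeneratorConfig", "generate_trial", "generate_complete_trial",
           "apply_mar_missingness", "write_dataset"]

# maskable instruments and the columns they cover at a visit
INSTRUMENTS = ("eq5d", "resources", "expenses", "pain")

# per-item (mu0, mu6, mu12) mean counts and NB dispersion, matched to the
# magnitude and overdispersion of available-case resource-use summaries
_RESOURCE_MEANS = {
    "hospital_outpatient": (1.78, 1.08, 1.13),
    "a_and_e": (0.10, 0.06, 0.04),
    "other_outpatient": (0.88, 0.42, 0.72),
    "gp_surgery": (2.20, 1.39, 1.40),
    "gp_home": (0.015, 0.015, 0.015),
    "nurse_surgery": (0.61, 0.58, 0.56),
    "other_primary_care": (0.22, 0.18, 0.08),
    "physiotherapist": (0.72, 0.26, 0.40),
    "occupational_therapist": (0.24, 0.06, 0.10),
    "other_community_care": (0.22, 0.12, 0.04),
}
_RESOURCE_DISPERSION = 0.8  # NB size parameter; var = mu + mu^2/size

_EXPENSE_PARAMS = {  # kind -> (P(any spend), mean £ given spend) per follow-up visit
    "otc": (0.45, 26.0),
    "childcare": (0.04, 70.0),
    "travel": (0.35, 21.0),
}

_MED_CATEGORY_PROBS = (0.18, 0.22, 0.30, 0.12, 0.18)  # over schema.MEDICATION_CATEGORIES


def _beta_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Shape parameters of a beta on [lo, hi] with the given mean and SD."""
    m = (mean - lo) / (hi - lo)
    v = (sd / (hi - lo)) ** 2
    if not 0 < m < 1 or v <= 0 or v >= m * (1 - m):
        raise ConfigurationError(
            f"no beta distribution on [{lo}, {hi}] has mean {mean} and sd {sd}")
    nu = m * (1 - m) / v - 1
    return m * nu, (1 - m) * nu


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic trial.

    Defaults reproduce the emulated trial: 124 per arm, baseline utility
    mean 0.61 (SD 0.18), a small QALY loss and cost saving in the
    intervention arm, and questionnaire missingness rising to ~25% by
    12 months.
    """

    n_per_arm: int = 124
    seed: int = 0

    # target complete-data arm contrasts (intervention - control)
    true_delta_cost: float = -11.80
    true_delta_qaly: float = -0.0052
    true_delta_pain6: float = 0.16
    true_delta_pain12: float = 0.10

    # utility process
    baseline_utility_mean: float = 0.61
    baseline_utility_sd: float = 0.18
    followup_utility_gain: float = 0.025
    utility_copula_rho: float = 0.6
    pain_level2_fraction: float = 0.97  # share restricted to pain/discomfort >= 2
    tariff_path: str | None = None      # generating tariff; default shipped table

    # cost process
    cost_shape_params: dict = field(default_factory=lambda: {
        item: {"means": _RESOURCE_MEANS[item], "dispersion": _RESOURCE_DISPERSION,
               "zero_inflation": 0.0}
        for item in schema.RESOURCE_ITEMS})
    med_cost_mean_intervention: float = 282.16
    med_cost_mean_control: float = 300.17
    med_uses_dispersion: float = 1.2
    hcq_dose_probs: tuple = (7 / 124, 85 / 124, 32 / 124)  # 200/300/400 mg
    hcq_full_duration_prob: float = 90 / 124
    hcq_partial_duration_range: tuple = (15, 308)
    drug_cfg: DrugCostConfig = field(default_factory=DrugCostConfig)

    # missingness
    missing_rate_by_visit: dict = field(default_factory=lambda: {
        "eq5d": {0: 0.01, 6: 0.155, 12: 0.24},
        "resources": {0: 0.02, 6: 0.16, 12: 0.25},
        "expenses": {0: 0.05, 6: 0.18, 12: 0.27},
        "pain": {0: 0.0, 6: 0.10, 12: 0.18},
    })
    mar_coefficients: dict = field(default_factory=lambda: {
        "age": 0.30, "baseline_pain_nrs": 0.35, "bmi": 0.10})
    monotone_bump: float = 1.0        # added to the 12m logit when 6m is missing
    instrument_coupling: float = 0.0  # copula correlation across instruments in a visit

    def validate(self) -> None:
        if self.n_per_arm < 2:
            raise ConfigurationError("n_per_arm must be >= 2")
        if self.baseline_utility_sd < 0:
            raise ConfigurationError("baseline_utility_sd must be >= 0")
        for instr, rates in self.missing_rate_by_visit.items():
            for v, p in rates.items():
                if not 0 <= p <= 1:
                    raise ConfigurationError(
                        f"missing rate for {instr} at {v}m is {p}, outside [0, 1]")
        if not 0 <= self.pain_level2_fraction <= 1:
            raise ConfigurationError("pain_level2_fraction must be in [0, 1]")
        if not 0 <= self.instrument_coupling < 1:
            raise ConfigurationError("instrument_coupling must be in [0, 1)")
        maskable = {"eq5d", "resources", "expenses", "pain", "u0", "u6", "u12"}
        bad = set(self.mar_coefficients) - set(schema.BASELINE_COVARIATES)
        if bad & maskable or bad:
            raise ConfigurationError(
                f"MAR coefficients may only reference always-observed baseline "
                f"fields {schema.BASELINE_COVARIATES}; got {sorted(bad)}")

    def tariff(self) -> TariffTable:
        return load_tariff(self.tariff_path or default_tariff_path())

    def expected_drug_cost(self) -> float:
        """Analytic mean HCQ cost per intervention participant."""
        lo, hi = self.hcq_partial_duration_range
        mean_days = (self.hcq_full_duration_prob * 365
                     + (1 - self.hcq_full_duration_prob) * (lo + hi) / 2)
        tablets = np.array([1.0, 1.5, 2.0]) @ np.asarray(self.hcq_dose_probs)
        return mean_days * tablets * self.drug_cfg.tablet_price

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["missing_rate_by_visit"] = {
            k: {str(t): p for t, p in v.items()} for k, v in d["missing_rate_by_visit"].items()}
        return json.dumps(d, indent=2, default=str)


# ---------------------------------------------------------------------------
# utility <-> EQ-5D profile


def _utility_to_levels(u: np.ndarray, tariff: TariffTable,
                       require_pain: np.ndarray) -> np.ndarray:
    """Nearest-tariff-utility inversion of latent utilities to 5-level profiles.

    `require_pain` marks participants restricted to pain/discomfort >= 2.
    Ties resolve deterministically to the first state in enumeration order.
    """
    states = all_states()
    out = np.empty((u.size, 5), dtype=int)
    for mask_pain in (False, True):
        rows = np.flatnonzero(require_pain == mask_pain)
        if not rows.size:
            continue
        cand = states[:, 3] >= 2 if mask_pain else np.ones(len(states), bool)
        vals = tariff.values[cand]
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        pos = np.searchsorted(sv, u[rows])
        pos = np.clip(pos, 1, sv.size - 1)
        pick = np.where(np.abs(sv[pos - 1] - u[rows]) <= np.abs(sv[pos] - u[rows]),
                        pos - 1, pos)
        out[rows] = states[cand][order[pick]]
    return out


# ---------------------------------------------------------------------------
# generation


def generate_complete_trial(config: GeneratorConfig) -> pd.DataFrame:
    """Fully observed synthetic dataset (no missingness applied)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_arm
    arm = np.repeat(["intervention", "control"], config.n_per_arm)
    interv = arm == "intervention"

    df = pd.DataFrame({
        "id": [f"P{i + 1:04d}" for i in range(n)],
        "arm": arm,
        "age": np.round(rng.normal(62.5, 9.0, n).clip(40, 90), 1),
        "gender": rng.choice(["F", "M"], n, p=[0.82, 0.18]),
        "bmi": np.round(rng.normal(28.0, 5.0, n).clip(16, 55), 1),
        "grip_strength": np.round(rng.gamma(9.0, 2.1, n), 1),
        "concomitant_analgesic": rng.binomial(1, 0.65, n),
    })

    # pain NRS: integer 0..10, moderate persistence, configured arm shift
    pain0_lat = rng.normal(6.2, 1.9, n)
    df["baseline_pain_nrs"] = np.round(pain0_lat).clip(0, 10).astype(int)
    for v, delta in ((6, config.true_delta_pain6), (12, config.true_delta_pain12)):
        lat = (2.4 + 0.55 * pain0_lat + delta * interv
               + rng.normal(0, 1.6, n))
        df[schema.pain_col(v)] = np.round(lat).clip(0, 10).astype(int)

    # utilities: Gaussian copula over visits, scaled-beta margins
    tariff = config.tariff()
    lo, hi = tariff.utility_range()
    rho = config.utility_copula_rho
    corr = np.full((3, 3), rho) + (1 - rho) * np.eye(3)
    z = rng.multivariate_normal(np.zeros(3), corr, size=n)
    p = stats.norm.cdf(z)
    shift = config.true_delta_qaly / 0.75
    require_pain = rng.random(n) < config.pain_level2_fraction
    for j, v in enumerate(schema.VISITS):
        mean = config.baseline_utility_mean + (config.followup_utility_gain if v else 0)
        a, b = _beta_params(mean, config.baseline_utility_sd, lo, hi)
        u = lo + (hi - lo) * special.betaincinv(a, b, p[:, j])
        if v:  # arm effect on follow-up utility only
            u = u + shift * interv
        df[schema.eq5d_cols(v)] = _utility_to_levels(u, tariff, require_pain)
        vas = 72 + 10 * z[:, j] + (2 if v else 0)
        df[schema.vas_col(v)] = np.round(vas).clip(0, 100).astype(int)

    # HCQ exposure (intervention arm only)
    dose = np.where(interv,
                    rng.choice([200, 300, 400], n, p=np.asarray(config.hcq_dose_probs)
                               / np.sum(config.hcq_dose_probs)),
                    np.nan)
    full = rng.random(n) < config.hcq_full_duration_prob
    d_lo, d_hi = config.hcq_partial_duration_range
    days = np.where(full, 365, rng.integers(d_lo, d_hi + 1, n))
    df["hcq_dose_mg"] = dose
    df["hcq_days"] = np.where(interv, days, np.nan)

    # resource-use counts: zero-inflated negative binomial per item/visit,
    # with the intervention outpatient intensity shifted to hit the cost target
    unit_costs = UnitCostTable.load()
    med_costs = MedicationCategoryCosts.load()
    cat_cost_vec = np.array([med_costs[c] for c in schema.MEDICATION_CATEGORIES])
    mean_cat_cost = cat_cost_vec @ np.asarray(_MED_CATEGORY_PROBS)

    resid = (config.true_delta_cost - config.expected_drug_cost()
             - (config.med_cost_mean_intervention - config.med_cost_mean_control))
    outp_shift = resid / unit_costs["hospital_outpatient"] / 2  # split over 6m & 12m

    for item in schema.RESOURCE_ITEMS:
        params = config.cost_shape_params[item]
        disp = params["dispersion"]
        zi = params["zero_inflation"]
        for j, v in enumerate(schema.VISITS):
            mu = np.full(n, params["means"][j], dtype=float)
            if item == "hospital_outpatient" and v != 0:
                mu = mu + outp_shift * interv
                if np.any(mu < 0):
                    raise ConfigurationError(
                        "true_delta_cost implies a negative outpatient visit rate; "
                        "choose a smaller cost contrast or larger base intensities")
            lam = rng.gamma(disp, mu / disp)      # gamma-Poisson => NB
            counts = rng.poisson(lam)
            if zi > 0:
                counts = np.where(rng.random(n) < zi, 0, counts)
            df[schema.resource_col(item, v)] = counts

    # medication-category uses over the four investigator forms
    lam_arm = np.where(interv,
                       config.med_cost_mean_intervention,
                       config.med_cost_mean_control) / (4 * mean_cat_cost)
    disp = config.med_uses_dispersion
    for cat, pc in zip(schema.MEDICATION_CATEGORIES, _MED_CATEGORY_PROBS):
        for interval in schema.MED_INTERVALS:
            lam = rng.gamma(disp, lam_arm * pc / disp)
            df[schema.med_col(cat, interval)] = rng.poisson(lam)

    # out-of-pocket expenses (£, zero-inflated gamma)
    for kind, (p_any, mean_spend) in _EXPENSE_PARAMS.items():
        for v in schema.VISITS:
            scale = 0.5 if v == 0 else 1.0
            spend = rng.gamma(1.2, mean_spend / 1.2, n) * scale
            any_ = rng.random(n) < p_any
            df[schema.expense_col(kind, v)] = np.round(np.where(any_, spend, 0.0), 2)

    return df[schema.all_columns()]


def _calibrated_mask(rng, x_lin: np.ndarray, target: float,
                     extra_logit: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Mask indicator with P(mask|x) = expit(a + x_lin + extra), a solved so the
    population rate equals `target`; `u` are (possibly coupled) uniforms."""
    if target <= 0:
        return np.zeros(x_lin.size, dtype=bool)
    if target >= 1:
        return np.ones(x_lin.size, dtype=bool)

    def rate(a):
        return special.expit(a + x_lin + extra_logit).mean() - target

    a = optimize.brentq(rate, -30, 30)
    return u < special.expit(a + x_lin + extra_logit)


def apply_mar_missingness(df: pd.DataFrame, config: GeneratorConfig,
                          seed: int | None = None) -> pd.DataFrame:
    """MAR masking overlay on a complete dataset.

    Masking depends only on always-observed baseline fields (via
    ``mar_coefficients``, applied to standardised covariates), so the
    mechanism is missing-at-random by construction.  Per-visit intercepts are
    calibrated so realised rates match ``missing_rate_by_visit`` in
    expectation; a participant whose 6-month instrument is missing gets an
    elevated 12-month logit (weak monotonicity), which the 12-month
    calibration accounts for.  Instruments within a visit can be coupled via
    a Gaussian copula (``instrument_coupling``); 0 means independence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    out = df.copy()
    n = len(df)

    x_lin = np.zeros(n)
    for cov, w in config.mar_coefficients.items():
        col = df[cov].astype(float)
        sd = col.std()
        x_lin += w * ((col - col.mean()) / sd if sd > 0 else 0.0).to_numpy()

    cols_by_instr = {
        "eq5d": lambda v: schema.eq5d_cols(v) + [schema.vas_col(v)],
        "resources": schema.resource_cols,
        "expenses": schema.expense_cols,
        "pain": lambda v: [schema.pain_col(v)] if v else [],
    }
    rho = config.instrument_coupling
    missing_prev = {instr: np.zeros(n, dtype=bool) for instr in INSTRUMENTS}
    for v in schema.VISITS:
        z_shared = rng.normal(size=n)
        for instr in INSTRUMENTS:
            cols = cols_by_instr[instr](v)
            if not cols:
                continue
            target = config.missing_rate_by_visit.get(instr, {}).get(v, 0.0)
            z = rho * z_shared + np.sqrt(1 - rho**2) * rng.normal(size=n)
            u = stats.norm.cdf(z)
            extra = config.monotone_bump * missing_prev[instr] if v == 12 else np.zeros(n)
            mask = _calibrated_mask(rng, x_lin, target, extra, u)
            out.loc[mask, cols] = np.nan
            if v == 6:
                missing_prev[instr] = mask
    return out


def generate_trial(config: GeneratorConfig) -> pd.DataFrame:
    """Complete generation then MAR masking; byte-identical under a fixed config."""
    return apply_mar_missingness(generate_complete_trial(config), config)


def write_dataset(df: pd.DataFrame, path, config: GeneratorConfig | None = None) -> None:
    """Write the canonical participant CSV (missing = empty field) plus, when a
    config is given, a sidecar ``<path>.truth.json`` of the generating
    parameters for recovery tests."""
    path = Path(path)
    df.to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        sidecar.write_text(config.to_json(), encoding="utf-8")
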