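"""End-to-end orchestration: scoring → costing → imputation → SUR/bootstrap →
decision outputs.

Analysis populations:

* ``itt_mi`` (base case) — all randomised participants; missing cost and
  utility components multiply imputed (MICE-PMM), SUR fitted per completed
  dataset and Rubin-pooled; bootstrap propagates imputation uncertainty
  ("boot_then_impute": resample participants stratified by arm, then run one
  stochastic imputation inside each replicate; the alternative
  "impute_then_boot" bootstraps within each completed dataset and pools the
  clouds);
* ``complete_case`` — sensitivity analysis dropping every participant with
  any missing modelled field (listwise);
* ``available_case`` — initial exploration: item-wise (pairwise) descriptives
  and unadjusted contrasts only.

All stochastic stages draw from seeds derived from one master seed, recorded
in the run log, and results are written only after the whole analysis has
succeeded (no partial outputs).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, schema
from .costing import (DrugCostConfig, MedicationCategoryCosts, UnitCostTable,
                      compute_cost_components)
from .decision import (DEFAULT_THRESHOLDS, ce_plane_export, ceac,
                       default_lambda_grid, icer, net_benefit)
from .eq5d import default_tariff_path, load_tariff, score_states
from .estimation import (BootstrapCloud, IncrementalResult, SurSpec, bca_interval,
                         bootstrap_cloud, fit_pain_mixed_model, fit_sur,
                         jackknife_values, percentile_interval)
from .imputation import ImputationSpec, _impute_once, mice_pmm, pool_rubin
from .qaly import qaly_auc_frame
from .schema import ConfigurationError, ValidationError

__all__ = ["RunConfig", "run_analysis", "describe_availability", "load_dataset",
           "prepare_components"]

UTILITY_COLS = ("u0", "u6", "u12")


@dataclass
class RunConfig:
    data_path: str
    output_dir: str
    perspective: str = "nhs_pss"            # nhs_pss | societal
    analysis_population: str = "itt_mi"     # itt_mi | complete_case | available_case
    B: int = 5000
    m: int | None = None                    # imputations; itt_mi default 20
    mice_iterations: int = 10
    boot_mice_iterations: int = 5           # cycles inside each bootstrap replicate
    pmm_donors: int = 5
    bootstrap_strategy: str = "boot_then_impute"
    seed: int = 0
    thresholds: tuple = DEFAULT_THRESHOLDS
    lambda_grid: tuple | None = None        # default 0..50k step 500
    tariff_path: str | None = None
    unit_cost_path: str | None = None
    med_cost_path: str | None = None
    interval_method: str = "bca"            # bca | percentile

    def validate(self) -> None:
        if self.perspective not in ("nhs_pss", "societal"):
            raise ConfigurationError(f"unknown perspective '{self.perspective}'")
        if self.analysis_population not in ("itt_mi", "complete_case", "available_case"):
            raise ConfigurationError(
                f"unknown analysis population '{self.analysis_population}'")
        if self.analysis_population == "complete_case" and self.m is not None:
            raise ConfigurationError(
                "complete_case analysis is imputation-free; do not set m")
        if self.bootstrap_strategy not in ("boot_then_impute", "impute_then_boot"):
            raise ConfigurationError(
                f"unknown bootstrap strategy '{self.bootstrap_strategy}'")
        if not Path(self.data_path).exists():
            raise ConfigurationError(f"data file not found: {self.data_path}")
        for p in (self.tariff_path, self.unit_cost_path, self.med_cost_path):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"referenced file not found: {p}")


def load_dataset(path) -> pd.DataFrame:
    """Read and validate the canonical participant CSV."""
    df = pd.read_csv(path)
    missing_cols = [c for c in schema.all_columns() if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols[:8]}"
                              + ("..." if len(missing_cols) > 8 else ""))
    bad_arm = df.index[~df["arm"].isin(schema.ARMS)]
    if len(bad_arm):
        raise ValidationError(f"{path}: row {bad_arm[0] + 2}: arm must be one of {schema.ARMS}")
    for v in schema.VISITS:
        for c in schema.eq5d_cols(v):
            col = df[c]
            bad = col.notna() & (~col.isin([1, 2, 3, 4, 5]))
            if bad.any():
                r = int(df.index[bad][0])
                raise ValidationError(
                    f"{path}: row {r + 2}, column {c}: EQ-5D level must be 1..5, "
                    f"got {col.iloc[r]!r}")
        for c in schema.resource_cols(v):
            col = df[c]
            bad = col.notna() & ((col < 0) | (col != col.round()))
            if bad.any():
                r = int(df.index[bad][0])
                raise ValidationError(
                    f"{path}: row {r + 2}, column {c}: resource count must be a "
                    f"nonnegative integer, got {col.iloc[r]!r}")
    return df


def prepare_components(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Score utilities and compute cost components on the raw dataset."""
    tariff = load_tariff(config.tariff_path or default_tariff_path())
    unit_costs = UnitCostTable.load(config.unit_cost_path)
    med_costs = MedicationCategoryCosts.load(config.med_cost_path)
    out = compute_cost_components(df, unit_costs, med_costs=med_costs)
    for u_col, v in zip(UTILITY_COLS, schema.VISITS):
        out[u_col] = score_states(df[schema.eq5d_cols(v)].to_numpy(float), tariff)
    return out


def _finalise_totals(df: pd.DataFrame, perspective: str) -> pd.DataFrame:
    """(Re)build QALY, perspective total and baseline-cost covariate from
    components; called after imputation so fill-ins flow through."""
    out = df.copy()
    out["qaly"] = qaly_auc_frame(out["u0"], out["u6"], out["u12"])
    nhs = (out["cost_resources_6m"] + out["cost_resources_12m"]
           + out["cost_drug"] + out["cost_medications"])
    if perspective == "societal":
        out["total_cost"] = nhs + out["cost_expenses_6m"] + out["cost_expenses_12m"]
        out["cost_baseline"] = out["cost_resources_0m"] + out["cost_expenses_0m"]
    else:
        out["total_cost"] = nhs
        out["cost_baseline"] = out["cost_resources_0m"]
    return out


def _imputable_cols(perspective: str) -> list[str]:
    cols = ["u0", "u6", "u12", "cost_resources_0m", "cost_resources_6m",
            "cost_resources_12m"]
    if perspective == "societal":
        cols += ["cost_expenses_0m", "cost_expenses_6m", "cost_expenses_12m"]
    return cols


def _modelled_fields(perspective: str) -> list[str]:
    return _imputable_cols(perspective) + [
        "baseline_pain_nrs", "concomitant_analgesic", "grip_strength",
        "bmi", "age", "gender"]


_MI_COVARIATES = ("baseline_pain_nrs", "concomitant_analgesic", "grip_strength",
                  "bmi", "age", "gender")


def describe_availability(df: pd.DataFrame) -> pd.DataFrame:
    """Per item × timepoint availability: n missing, % missing, available-case
    mean and SD (pairwise deletion)."""
    rows = []
    groups = {"resource": [(i, schema.resource_col(i, v), v)
                           for i in schema.RESOURCE_ITEMS for v in schema.VISITS],
              "eq5d_utility_visit": [("eq5d", schema.eq5d_col("mo", v), v)
                                     for v in schema.VISITS],
              "expense": [(k, schema.expense_col(k, v), v)
                          for k in schema.EXPENSE_KINDS for v in schema.VISITS]}
    for kind, entries in groups.items():
        for item, col, v in entries:
            for arm in schema.ARMS:
                s = df.loc[df["arm"] == arm, col]
                n_miss = int(s.isna().sum())
                rows.append({
                    "kind": kind, "item": item, "visit_months": v, "arm": arm,
                    "n": len(s), "n_missing": n_miss,
                    "pct_missing": round(100 * n_miss / len(s), 1),
                    "mean": float(s.mean()) if s.notna().any() else float("nan"),
                    "sd": float(s.std()) if s.notna().sum() > 1 else float("nan"),
                })
    return pd.DataFrame(rows)


def _sur_statistic(spec: SurSpec):
    def stat(sample: pd.DataFrame):
        r = fit_sur(sample, spec)
        return r.delta_cost, r.delta_qaly
    return stat


def run_analysis(config: RunConfig) -> dict:
    """Execute the configured analysis; returns the result bundle and writes
    summary.json, ceac.csv, ce_plane.csv, availability.csv and run.log to the
    output directory (only on success)."""
    config.validate()
    raw = load_dataset(config.data_path)
    comp = prepare_components(raw, config)
    availability = describe_availability(raw)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(child.generate_state(1)[0] % (2**31))
             for name, child in zip(
                 ("imputation", "bootstrap", "jackknife"), ss.spawn(3))}

    bundle: dict = {
        # output_dir is omitted so reruns into different directories compare
        # byte-identical
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()
                   if k != "output_dir"},
        "seeds": seeds,
        "versions": {"trialcea": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "n_randomised": int(len(raw)),
        "n_per_arm": {a: int((raw["arm"] == a).sum()) for a in schema.ARMS},
    }

    perspective = config.perspective
    sur_spec = SurSpec()
    grid = (np.asarray(config.lambda_grid, float) if config.lambda_grid is not None
            else default_lambda_grid())

    if config.analysis_population == "available_case":
        full = _finalise_totals(comp, perspective)
        by_arm = full.groupby("arm")
        bundle["available_case"] = {
            "mean_qaly": {a: float(g["qaly"].mean()) for a, g in by_arm},
            "mean_total_cost": {a: float(g["total_cost"].mean()) for a, g in by_arm},
            "unadjusted_delta_qaly": float(
                full.loc[full.arm == "intervention", "qaly"].mean()
                - full.loc[full.arm == "control", "qaly"].mean()),
            "unadjusted_delta_cost": float(
                full.loc[full.arm == "intervention", "total_cost"].mean()
                - full.loc[full.arm == "control", "total_cost"].mean()),
        }
        _write_outputs(config, bundle, availability, None, None)
        return bundle

    if config.analysis_population == "complete_case":
        modelled = _modelled_fields(perspective)
        cc = comp.dropna(subset=modelled).reset_index(drop=True)
        bundle["n_analysed"] = int(len(cc))
        bundle["pct_complete"] = round(100 * len(cc) / len(raw), 1)
        data_cc = _finalise_totals(cc, perspective)
        point = fit_sur(data_cc, sur_spec)
        stat = _sur_statistic(sur_spec)
        cloud = bootstrap_cloud(data_cc, lambda s, rng: stat(s), B=config.B,
                                seed=seeds["bootstrap"])
        jack = jackknife_values(data_cc, stat)
    else:  # itt_mi
        m = config.m or 20
        ispec = ImputationSpec(m=m, iterations=config.mice_iterations,
                               pmm_donors=config.pmm_donors,
                               model_covariates=_MI_COVARIATES,
                               seed=seeds["imputation"])
        impute_cols = _imputable_cols(perspective)
        completed = mice_pmm(comp, impute_cols, ispec)
        fits = [fit_sur(_finalise_totals(d, perspective), sur_spec) for d in completed]
        dc, tc, _ = pool_rubin([f.delta_cost for f in fits],
                               [f.var_cost for f in fits],
                               dfcom=len(comp) - 10)
        de, te, _ = pool_rubin([f.delta_qaly for f in fits],
                               [f.var_qaly for f in fits],
                               dfcom=len(comp) - 10)
        point = IncrementalResult(delta_cost=dc, delta_qaly=de,
                                  var_cost=tc, var_qaly=te)
        bundle["n_analysed"] = int(len(comp))
        bundle["m_imputations"] = m
        boot_spec = ImputationSpec(m=2, iterations=config.boot_mice_iterations,
                                   pmm_donors=config.pmm_donors,
                                   model_covariates=_MI_COVARIATES,
                                   seed=seeds["imputation"])

        def impute_once_then_sur(sample: pd.DataFrame, rng):
            filled = _impute_once(sample, impute_cols, boot_spec, rng)
            r = fit_sur(_finalise_totals(filled, perspective), sur_spec)
            return r.delta_cost, r.delta_qaly

        if config.bootstrap_strategy == "boot_then_impute":
            cloud = bootstrap_cloud(comp, impute_once_then_sur, B=config.B,
                                    seed=seeds["bootstrap"])
        else:  # impute_then_boot: within-dataset clouds, pooled
            stat = _sur_statistic(sur_spec)
            per = int(np.ceil(config.B / m))
            parts = [bootstrap_cloud(_finalise_totals(d, perspective),
                                     lambda s, rng: stat(s), B=per,
                                     seed=seeds["bootstrap"] + i)
                     for i, d in enumerate(completed)]
            cloud = BootstrapCloud(
                delta_cost=np.concatenate([p.delta_cost for p in parts])[:config.B],
                delta_qaly=np.concatenate([p.delta_qaly for p in parts])[:config.B],
                seed=seeds["bootstrap"])

        jack_rng = np.random.default_rng(seeds["jackknife"])

        def jack_stat(sub: pd.DataFrame):
            filled = _impute_once(sub, impute_cols, boot_spec, jack_rng)
            r = fit_sur(_finalise_totals(filled, perspective), sur_spec)
            return r.delta_cost, r.delta_qaly

        jack = jackknife_values(comp, jack_stat)

    # intervals and decision outputs (common to itt_mi / complete_case)
    if config.interval_method == "bca":
        ci_cost = bca_interval(cloud.delta_cost, point.delta_cost, jack[:, 0])
        ci_qaly = bca_interval(cloud.delta_qaly, point.delta_qaly, jack[:, 1])
    else:
        ci_cost = percentile_interval(cloud.delta_cost)
        ci_qaly = percentile_interval(cloud.delta_qaly)
    point.ci_cost, point.ci_qaly = ci_cost, ci_qaly
    point.method = config.interval_method

    ic = icer(point.delta_cost, point.delta_qaly)
    nb_out = {}
    for lam in config.thresholds:
        nb_point = float(net_benefit(point.delta_cost, point.delta_qaly, lam))
        nb_rep = net_benefit(cloud.delta_cost, cloud.delta_qaly, lam)
        nb_jack = net_benefit(jack[:, 0], jack[:, 1], lam)
        if config.interval_method == "bca":
            nb_ci = bca_interval(nb_rep, nb_point, nb_jack)
        else:
            nb_ci = percentile_interval(nb_rep)
        nb_out[f"{int(lam)}"] = {"value": round(nb_point, 4),
                                 "ci": [round(nb_ci[0], 4), round(nb_ci[1], 4)]}

    ceac_df = ceac(cloud, grid)
    plane_df, shares = ce_plane_export(cloud)

    bundle.update({
        "delta_cost": round(point.delta_cost, 6),
        "delta_qaly": round(point.delta_qaly, 8),
        "ci_cost": [round(x, 4) for x in ci_cost],
        "ci_qaly": [round(x, 6) for x in ci_qaly],
        "interval_method": config.interval_method,
        "icer": {"value": None if ic.value is None else round(ic.value, 2),
                 "quadrant": ic.quadrant, "interpretation": ic.interpretation},
        "net_benefit": nb_out,
        "ceac_at_thresholds": {f"{int(lam)}": _ceac_at(cloud, lam)
                               for lam in config.thresholds},
        "quadrant_shares": shares,
        "bootstrap": {"B": int(cloud.B), "n_failed": int(cloud.n_failed),
                      "strategy": (config.bootstrap_strategy
                                   if config.analysis_population == "itt_mi"
                                   else "plain")},
    })

    # pain outcome (available-case; exchangeable-covariance GLS)
    pain_long = _pain_long(raw)
    if pain_long["pain"].notna().any():
        pm = fit_pain_mixed_model(pain_long)
        eff6 = pm["effects_by_visit"].get(6)
        bundle["pain"] = {
            "effects_by_visit": {str(v): {"effect": round(e, 4), "se": round(s, 4)}
                                 for v, (e, s) in pm["effects_by_visit"].items()},
            "rho": round(pm["rho"], 4),
            "icer_note": ("no pain reduction at 6 months - cost per unit of pain "
                          "reduction not meaningful" if eff6 and eff6[0] >= 0 else
                          "pain reduction observed"),
        }

    _write_outputs(config, bundle, availability, ceac_df, plane_df)
    return bundle


def _ceac_at(cloud: BootstrapCloud, lam: float) -> float:
    return float(np.mean(lam * cloud.delta_qaly - cloud.delta_cost > 0))


def _pain_long(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for v in (6, 12):
        rows.append(pd.DataFrame({
            "id": df["id"], "arm": df["arm"], "visit": v,
            "baseline_pain_nrs": df["baseline_pain_nrs"],
            "pain": df[schema.pain_col(v)],
        }))
    return pd.concat(rows, ignore_index=True)


def _write_outputs(config: RunConfig, bundle: dict, availability: pd.DataFrame,
                   ceac_df, plane_df) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    availability.to_csv(out / "availability.csv", index=False)
    if ceac_df is not None:
        ceac_df.to_csv(out / "ceac.csv", index=False)
    if plane_df is not None:
        plane_df.to_csv(out / "ce_plane.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    log_lines = [f"trialcea {__version__}",
                 f"analysis_population={config.analysis_population}",
                 f"perspective={config.perspective}",
                 f"master_seed={config.seed}"]
    log_lines += [f"seed.{k}={v}" for k, v in bundle["seeds"].items()]
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
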