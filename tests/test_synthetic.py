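"""Generator contracts: balance, determinism, calibration, MAR structure."""

import numpy as np
import pandas as pd
import pytest

from trialcea import schema
from trialcea.pipeline import prepare_components, _finalise_totals, RunConfig
from trialcea.schema import ConfigurationError
from trialcea.synthetic import (GeneratorConfig, apply_mar_missingness,
                                generate_complete_trial, generate_trial,
                                write_dataset)


def _no_missing_config(**kw):
    rates = {i: {0: 0.0, 6: 0.0, 12: 0.0} for i in ("eq5d", "resources", "expenses", "pain")}
    return GeneratorConfig(missing_rate_by_visit=rates, **kw)


def test_record_count_and_balance(small_trial):
    assert len(small_trial) == 248
    assert small_trial["arm"].value_counts().to_dict() == {
        "intervention": 124, "control": 124}


def test_zero_missing_rates_give_complete_data():
    df = generate_trial(_no_missing_config(n_per_arm=40, seed=2))
    ctrl = df[df.arm == "control"].drop(columns=["hcq_dose_mg", "hcq_days"])
    interv = df[df.arm == "intervention"]
    assert not ctrl.isna().any().any()
    assert not interv.isna().any().any()


def test_same_seed_reproduces_byte_identical(tmp_path):
    cfg = GeneratorConfig(n_per_arm=30, seed=9)
    a, b = generate_trial(cfg), generate_trial(GeneratorConfig(n_per_arm=30, seed=9))
    pd.testing.assert_frame_equal(a, b)
    write_dataset(a, tmp_path / "a.csv", cfg)
    write_dataset(b, tmp_path / "b.csv", cfg)
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
    assert (tmp_path / "a.csv.truth.json").exists()


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        generate_trial(GeneratorConfig(n_per_arm=1))
    with pytest.raises(ConfigurationError):
        generate_trial(GeneratorConfig(missing_rate_by_visit={"eq5d": {6: 1.4}}))
    with pytest.raises(ConfigurationError):
        generate_trial(GeneratorConfig(baseline_utility_sd=-0.1))


def test_mar_cannot_reference_maskable_fields():
    with pytest.raises(ConfigurationError, match="baseline"):
        generate_trial(GeneratorConfig(mar_coefficients={"u12": 1.0}))


def test_masking_preserves_complete_values(small_trial, small_trial_complete):
    """Missingness is an overlay: every observed cell equals the complete value."""
    obs = small_trial.notna()
    for c in small_trial.columns:
        pd.testing.assert_series_equal(small_trial.loc[obs[c], c],
                                       small_trial_complete.loc[obs[c], c],
                                       check_dtype=False)


def test_realised_missing_fraction_within_binomial_bound():
    cfg = GeneratorConfig(n_per_arm=124, seed=21)
    df = generate_trial(cfg)
    n = len(df)
    for instr, col in (("eq5d", schema.eq5d_col("mo", 12)),
                       ("resources", schema.resource_col("gp_surgery", 6))):
        visit = int(col.rsplit("_", 1)[1][:-1])
        p = cfg.missing_rate_by_visit[instr][visit]
        frac = df[col].isna().mean()
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)


def test_missingness_weakly_monotone_over_visits():
    cfg = GeneratorConfig(n_per_arm=3000, seed=4)
    df = generate_trial(cfg)
    m6 = df[schema.eq5d_col("mo", 6)].isna()
    m12 = df[schema.eq5d_col("mo", 12)].isna()
    assert m12[m6].mean() > m12[~m6].mean() + 0.05


def test_complete_data_contrasts_converge_to_truth():
    """Law of large numbers: complete-data arm contrasts near the configured
    true effects, within 3 Monte-Carlo standard errors."""
    cfg = GeneratorConfig(n_per_arm=5000, true_delta_qaly=-0.0052, seed=13)
    df = generate_complete_trial(cfg)
    comp = prepare_components(df, RunConfig(data_path=".", output_dir="."))
    full = _finalise_totals(comp, "nhs_pss")
    iv = full["arm"] == "intervention"
    for col, truth in (("qaly", cfg.true_delta_qaly), ("total_cost", cfg.true_delta_cost)):
        delta = full.loc[iv, col].mean() - full.loc[~iv, col].mean()
        mc_se = np.sqrt(full[col].var() * 2 / cfg.n_per_arm)
        assert abs(delta - truth) <= 3 * mc_se


def test_arm_independent_of_outcomes_when_deltas_zero():
    """Permutation test at alpha = 0.01 on the QALY contrast under null deltas."""
    cfg = _no_missing_config(n_per_arm=1500, seed=17, true_delta_cost=0.0,
                             true_delta_qaly=0.0, true_delta_pain6=0.0,
                             true_delta_pain12=0.0,
                             med_cost_mean_intervention=290.0,
                             med_cost_mean_control=290.0)
    # exclude the structural drug cost: with all configured deltas zero the
    # remaining outcome processes must be arm-exchangeable
    df = generate_complete_trial(cfg)
    comp = prepare_components(df, RunConfig(data_path=".", output_dir="."))
    full = _finalise_totals(comp, "nhs_pss")
    rng = np.random.default_rng(0)
    iv = (full["arm"] == "intervention").to_numpy()
    for col in ("qaly",):
        x = full[col].to_numpy()
        obs = abs(x[iv].mean() - x[~iv].mean())
        perms = np.array([
            abs(x[p].mean() - x[~p].mean())
            for p in (rng.permutation(iv) for _ in range(500))])
        pval = (np.sum(perms >= obs) + 1) / 501
        assert pval > 0.01


def test_pain_discomfort_mostly_above_level_one(small_trial_complete):
    pd_cols = [schema.eq5d_col("pd", v) for v in schema.VISITS]
    frac = (small_trial_complete[pd_cols] >= 2).to_numpy().mean()
    assert frac >= 0.95


def test_hcq_exposure_only_in_intervention(small_trial_complete):
    ctrl = small_trial_complete[small_trial_complete.arm == "control"]
    assert ctrl["hcq_dose_mg"].isna().all() and ctrl["hcq_days"].isna().all()
    iv = small_trial_complete[small_trial_complete.arm == "intervention"]
    assert iv["hcq_dose_mg"].isin([200, 300, 400]).all()
    assert iv["hcq_days"].between(0, 365).all()


def test_csv_roundtrip(tmp_path, small_trial):
    from trialcea.pipeline import load_dataset
    write_dataset(small_trial, tmp_path / "d.csv")
    back = load_dataset(tmp_path / "d.csv")
    assert list(back.columns) == list(small_trial.columns)
    assert len(back) == len(small_trial)
    np.testing.assert_allclose(back["bmi"], small_trial["bmi"])
    assert back[schema.eq5d_col("pd", 12)].isna().equals(
        small_trial[schema.eq5d_col("pd", 12)].isna())
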