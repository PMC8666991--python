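"""SUR, bootstrap, BCa and the exchangeable-covariance pain model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from trialcea.estimation import (BootstrapCloud, SurSpec, bca_interval,
                                 bootstrap_cloud, fit_pain_mixed_model, fit_sur,
                                 jackknife_values, percentile_interval)
from trialcea.schema import ValidationError


def _ols_arm_coefs(df):
    X = np.column_stack([
        np.ones(len(df)), (df["arm"] == "intervention").astype(float),
        df["u0"], df["cost_baseline"], df["baseline_pain_nrs"],
        df["concomitant_analgesic"], df["grip_strength"], df["bmi"], df["age"],
        (df["gender"] == "F").astype(float)])
    c = sm.OLS(df["total_cost"].to_numpy(), X).fit().params[1]
    q = sm.OLS(df["qaly"].to_numpy(), X).fit().params[1]
    return c, q


def test_sur_equals_ols_with_identical_regressors(regression_frame):
    """Classical identity, checked numerically to 1e-8 against statsmodels OLS."""
    r = fit_sur(regression_frame)
    ols_c, ols_q = _ols_arm_coefs(regression_frame)
    assert abs(r.delta_cost - ols_c) < 1e-8
    assert abs(r.delta_qaly - ols_q) < 1e-8


def test_sur_rejects_missing_and_collinear(regression_frame):
    df = regression_frame.copy()
    df.loc[0, "qaly"] = np.nan
    with pytest.raises(ValidationError, match="missing"):
        fit_sur(df)
    df2 = regression_frame.copy()
    df2["bmi"] = df2["age"] * 2  # exact collinearity
    with pytest.raises(ValidationError, match="collinear"):
        fit_sur(df2)


def test_bootstrap_basic_contracts(regression_frame):
    stat = lambda s, rng: (s["total_cost"].mean(), s["qaly"].mean())
    one = bootstrap_cloud(regression_frame, stat, B=1, seed=0)
    assert one.B == 1
    a = bootstrap_cloud(regression_frame, stat, B=50, seed=42)
    b = bootstrap_cloud(regression_frame, stat, B=50, seed=42)
    np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
    np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)


def test_bootstrap_stratification_preserves_arm_sizes(regression_frame):
    def stat(s, rng):
        assert (s["arm"] == "intervention").sum() == 200
        assert (s["arm"] == "control").sum() == 200
        return 0.0, 0.0
    bootstrap_cloud(regression_frame, stat, B=5, seed=1)


def test_bootstrap_cloud_mean_near_point_estimate(regression_frame):
    r = fit_sur(regression_frame)
    def stat(s, rng):
        f = fit_sur(s)
        return f.delta_cost, f.delta_qaly
    cloud = bootstrap_cloud(regression_frame, stat, B=600, seed=3)
    se_c = cloud.delta_cost.std() / np.sqrt(cloud.B)
    se_q = cloud.delta_qaly.std() / np.sqrt(cloud.B)
    assert abs(cloud.delta_cost.mean() - r.delta_cost) < 4 * se_c
    assert abs(cloud.delta_qaly.mean() - r.delta_qaly) < 4 * se_q


def test_bootstrap_failure_policy(regression_frame):
    calls = {"n": 0}
    def flaky(s, rng):
        calls["n"] += 1
        if calls["n"] % 3 == 0:
            raise RuntimeError("boom")
        return 0.0, 0.0
    with pytest.raises(RuntimeError, match="replicates failed"):
        bootstrap_cloud(regression_frame, flaky, B=100, seed=0)


def test_bca_reduces_to_percentile_under_forced_zero_corrections():
    rng = np.random.default_rng(1)
    v = rng.gamma(2, 1, 5000)
    lo, hi = bca_interval(v, float(np.median(v)), jackknife=np.zeros(10),
                         z0=0.0, accel=0.0)
    plo, phi = percentile_interval(v)
    assert lo == pytest.approx(plo) and hi == pytest.approx(phi)


def test_bca_z0_zero_when_half_below():
    rng = np.random.default_rng(2)
    v = np.sort(rng.normal(0, 1, 4000))
    point = float(np.median(v))  # exactly half strictly below (up to ties)
    jk = rng.normal(0, 1, 50)
    jk = np.concatenate([jk, -jk])  # symmetric jackknife -> accel ~ 0
    lo, hi = bca_interval(v, point, jk)
    plo, phi = percentile_interval(v)
    assert lo == pytest.approx(plo, abs=0.05)
    assert hi == pytest.approx(phi, abs=0.05)


def test_bca_degenerate_cloud():
    v = np.full(500, 3.3)
    assert bca_interval(v, 3.3, np.full(10, 3.3)) == (3.3, 3.3)


def test_bca_needs_enough_replicates():
    with pytest.raises(ValidationError):
        bca_interval(np.arange(50.0), 25.0, np.arange(10.0))


def test_bca_matches_scipy_on_skewed_mean():
    """Independent oracle: scipy.stats.bootstrap(method='BCa') on the same data."""
    from scipy.stats import bootstrap as scipy_bootstrap
    rng = np.random.default_rng(7)
    x = rng.exponential(1.0, 80)
    res = scipy_bootstrap((x,), np.mean, n_resamples=4000, method="BCa",
                          confidence_level=0.95, random_state=np.random.default_rng(1))
    idx = np.random.default_rng(2).integers(0, x.size, (4000, x.size))
    boot = x[idx].mean(axis=1)
    jack = (x.sum() - x) / (x.size - 1)
    lo, hi = bca_interval(boot, float(x.mean()), jack)
    width = res.confidence_interval.high - res.confidence_interval.low
    assert lo == pytest.approx(res.confidence_interval.low, abs=0.1 * width)
    assert hi == pytest.approx(res.confidence_interval.high, abs=0.1 * width)


def test_percentile_endpoints_are_cloud_order_statistics():
    rng = np.random.default_rng(3)
    v = rng.normal(0, 1, 999)
    lo, hi = percentile_interval(v)
    assert lo >= v.min() and hi <= v.max()
    assert np.mean(v < lo) <= 0.025 + 2 / v.size
    assert np.mean(v > hi) <= 0.025 + 2 / v.size


# ---------------------------------------------------------------------------
# pain model


def _pain_long(n_per_arm=150, rho=0.5, delta=0.4, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    arm = np.repeat(["intervention", "control"], n_per_arm)
    base = rng.integers(2, 9, n).astype(float)
    person = rng.normal(0, np.sqrt(rho), n)
    rows = []
    for v in (6, 12):
        eps = rng.normal(0, np.sqrt(1 - rho), n)
        pain = 1.0 + 0.6 * base + delta * (arm == "intervention") + person + eps
        rows.append(pd.DataFrame({"id": [f"p{i}" for i in range(n)], "arm": arm,
                                  "visit": v, "baseline_pain_nrs": base,
                                  "pain": pain}))
    return pd.concat(rows, ignore_index=True)


def test_pain_model_equals_ols_when_rho_zero():
    long = _pain_long(rho=0.0, seed=1)
    fit = fit_pain_mixed_model(long)
    X = np.column_stack([
        np.ones(len(long)), (long["arm"] == "intervention").astype(float),
        (long["visit"] == 12).astype(float),
        ((long["visit"] == 12) & (long["arm"] == "intervention")).astype(float),
        long["baseline_pain_nrs"]])
    ols = sm.OLS(long["pain"], X).fit().params
    assert abs(fit["rho"]) < 0.1  # moment estimate near zero
    assert fit["effects_by_visit"][6][0] == pytest.approx(ols.iloc[1], abs=0.02)


def test_pain_model_duplicate_observation_invariance():
    """GLS weighting oracle: for a balanced design with person-constant
    regressors, duplicating every observation leaves the arm effect unchanged
    under compound symmetry (per-person weights cancel)."""
    toy = pd.DataFrame({
        "id": np.repeat([f"p{i}" for i in range(6)], 2),
        "arm": np.repeat(["intervention"] * 3 + ["control"] * 3, 2),
        "visit": [6, 12] * 6,
        "baseline_pain_nrs": np.repeat([5.0, 6.0, 7.0, 4.0, 6.0, 5.0], 2),
        "pain": [5, 6, 7, 6, 4, 5, 6, 7, 5, 4, 6, 6.0],
    })
    single = fit_pain_mixed_model(toy, visit_effects=False)
    doubled = fit_pain_mixed_model(pd.concat([toy, toy], ignore_index=True),
                                   visit_effects=False)
    assert (doubled["effects_by_visit"][6][0]
            == pytest.approx(single["effects_by_visit"][6][0], abs=1e-9))


def test_pain_model_recovers_arm_shift():
    long = _pain_long(n_per_arm=1500, rho=0.5, delta=0.16, seed=5)
    fit = fit_pain_mixed_model(long)
    eff, se = fit["effects_by_visit"][6]
    assert abs(eff - 0.16) <= 3 * se
    assert 0.3 < fit["rho"] < 0.7


def test_jackknife_shape(regression_frame):
    sub = regression_frame.head(40)
    jk = jackknife_values(sub, lambda d: (d["qaly"].mean(), d["total_cost"].mean()))
    assert jk.shape == (40, 2)
    assert np.isfinite(jk).all()
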