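"""Adjusted between-arm incremental costs and QALYs.

Point estimates come from a seemingly-unrelated-regression (SUR) system of
two equations — total cost and QALYs, each regressed on the arm indicator and
the adjustment covariates (baseline utility, baseline cost and the clinical
analysis covariates) — estimated by feasible GLS: equation-by-equation OLS,
residual cross-equation covariance, then joint GLS.  The arm coefficients are
the incremental cost ΔC and incremental QALYs ΔE.  When both equations carry
identical regressors, SUR coincides with per-equation OLS (classical result,
used as an oracle in the test suite); the cross-equation step matters when
regressor sets differ or when restrictions are imposed.

Uncertainty is quantified by non-parametric bootstrap: participants are
resampled with replacement, stratified by arm (conditioning on the 1:1
design), the full pipeline statistic is recomputed per replicate, and the B
(ΔC, ΔE) pairs form the cost-effectiveness-plane cloud.  Intervals are
bias-corrected and accelerated (BCa): the bias constant z0 comes from the
fraction of replicates below the point estimate, the acceleration a from the
skewness of leave-one-participant-out jackknife values.

The cost-effectiveness analysis of the pain outcome uses a repeated-measures
GLS with exchangeable (compound-symmetry) covariance: equal variance and a
common within-person correlation across visits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import ConfigurationError, ValidationError

__all__ = ["SurSpec", "IncrementalResult", "BootstrapCloud", "fit_sur",
           "bootstrap_cloud", "jackknife_values", "bca_interval",
           "percentile_interval", "fit_pain_mixed_model"]

DEFAULT_SUR_COVARIATES = (
    "u0", "cost_baseline", "baseline_pain_nrs", "concomitant_analgesic",
    "grip_strength", "bmi", "age", "gender",
)


@dataclass
class SurSpec:
    outcome_cost: str = "total_cost"
    outcome_qaly: str = "qaly"
    covariates: tuple = DEFAULT_SUR_COVARIATES
    arm_col: str = "arm"


@dataclass
class IncrementalResult:
    delta_cost: float
    delta_qaly: float
    var_cost: float = float("nan")
    var_qaly: float = float("nan")
    ci_cost: tuple | None = None
    ci_qaly: tuple | None = None
    method: str = "bca"


@dataclass
class BootstrapCloud:
    """B bootstrap replicates of (ΔC, ΔE)."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int | None = None
    n_failed: int = 0

    def __post_init__(self):
        self.delta_cost = np.asarray(self.delta_cost, float)
        self.delta_qaly = np.asarray(self.delta_qaly, float)
        if self.delta_cost.size != self.delta_qaly.size or self.delta_cost.size < 1:
            raise ValidationError("cloud needs B >= 1 matched (ΔC, ΔE) pairs")

    @property
    def B(self) -> int:
        return self.delta_cost.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": np.arange(1, self.B + 1),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
        })


def _design_matrix(df: pd.DataFrame, covariates, arm_col: str):
    cols = {"const": np.ones(len(df)),
            "arm": (df[arm_col] == "intervention").astype(float).to_numpy()}
    for c in covariates:
        x = df[c]
        if x.dtype == object:
            x = (x == "F").astype(float)
        cols[c] = np.asarray(x, float)
    names = list(cols)
    X = np.column_stack(list(cols.values()))
    if not np.all(np.isfinite(X)):
        bad = [n for n, col in cols.items() if not np.all(np.isfinite(col))]
        raise ValidationError(f"missing values in modelled fields: {bad} "
                              "(impute or drop before estimation)")
    return X, names


def _check_rank(X: np.ndarray, names) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name columns whose removal restores full column rank
        collinear = [names[j] for j in range(X.shape[1])
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == r]
        raise ValidationError(f"singular design matrix; collinear columns: {collinear}")


def fit_sur(df: pd.DataFrame, spec: SurSpec | None = None) -> IncrementalResult:
    """Feasible-GLS SUR of (total cost, QALY) on arm + covariates.

    Returns the arm coefficients (ΔC, ΔE) and their asymptotic variances from
    the joint GLS covariance.
    """
    spec = spec or SurSpec()
    y1 = df[spec.outcome_cost].to_numpy(float)
    y2 = df[spec.outcome_qaly].to_numpy(float)
    if np.isnan(y1).any() or np.isnan(y2).any():
        raise ValidationError("missing outcome values; SUR runs post-imputation "
                              "or on complete cases")
    X, names = _design_matrix(df, spec.covariates, spec.arm_col)
    _check_rank(X, names)
    n, p = X.shape

    # stage 1: per-equation OLS
    XtX_inv = np.linalg.inv(X.T @ X)
    b1 = XtX_inv @ (X.T @ y1)
    b2 = XtX_inv @ (X.T @ y2)
    e1, e2 = y1 - X @ b1, y2 - X @ b2

    # stage 2: residual covariance and joint GLS.  With a common regressor
    # matrix the GLS step reproduces OLS exactly; it is retained because the
    # joint covariance of (ΔC, ΔE) needs the cross-equation correlation and
    # because callers may restrict covariates per equation via subclassing.
    S = np.cov(np.vstack([e1, e2]), ddof=p)
    S_inv = np.linalg.inv(S)
    A = np.kron(S_inv, X.T @ X)
    rhs = np.concatenate([
        S_inv[0, 0] * X.T @ y1 + S_inv[0, 1] * X.T @ y2,
        S_inv[1, 0] * X.T @ y1 + S_inv[1, 1] * X.T @ y2,
    ])
    beta = np.linalg.solve(A, rhs)
    cov_beta = np.linalg.inv(A)
    j = names.index("arm")
    return IncrementalResult(
        delta_cost=float(beta[j]),
        delta_qaly=float(beta[p + j]),
        var_cost=float(cov_beta[j, j]),
        var_qaly=float(cov_beta[p + j, p + j]),
    )


def bootstrap_cloud(df: pd.DataFrame, statistic, B: int = 5000,
                    seed: int | None = None, stratify_col: str = "arm",
                    max_failure_rate: float = 0.01) -> BootstrapCloud:
    """Stratified (by arm) participant-level resampling of a pipeline statistic.

    `statistic(resampled_df, rng)` must return a (ΔC, ΔE) pair; it may embed
    arbitrary pipeline stages (costing, imputation, SUR).  A replicate whose
    statistic raises is recorded as failed; the run aborts if more than
    `max_failure_rate` of replicates fail.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(df[stratify_col] == g) for g in df[stratify_col].unique()]
    dc, de = np.full(B, np.nan), np.full(B, np.nan)
    failed = 0
    for b in range(B):
        idx = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in groups])
        sample = df.iloc[idx].reset_index(drop=True)
        try:
            dc[b], de[b] = statistic(sample, rng)
        except Exception:
            failed += 1
            if failed > max_failure_rate * B:
                raise RuntimeError(
                    f"{failed}/{b + 1} bootstrap replicates failed "
                    f"(> {max_failure_rate:.0%} of B={B})")
    ok = ~np.isnan(dc)
    return BootstrapCloud(delta_cost=dc[ok], delta_qaly=de[ok],
                          seed=seed, n_failed=failed)


def jackknife_values(df: pd.DataFrame, statistic) -> np.ndarray:
    """Leave-one-participant-out statistic values, shape (n, n_outputs)."""
    vals = []
    for i in range(len(df)):
        sub = df.drop(df.index[i]).reset_index(drop=True)
        vals.append(np.atleast_1d(np.asarray(statistic(sub), float)))
    return np.vstack(vals)


def percentile_interval(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    alpha = (1 - level) / 2
    lo, hi = np.quantile(values, [alpha, 1 - alpha])
    return float(lo), float(hi)


def bca_interval(values: np.ndarray, point: float, jackknife: np.ndarray,
                 level: float = 0.95, z0: float | None = None,
                 accel: float | None = None) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval.

    z0 is Φ⁻¹ of the fraction of replicates strictly below the point estimate;
    the acceleration a is the jackknife-skewness estimate
    a = Σd³ / (6 (Σd²)^{3/2}) with d the deviations of the jackknife mean from
    each leave-one-out value.  Forcing z0 = a = 0 (via the keyword overrides)
    reproduces the percentile interval exactly.
    """
    v = np.asarray(values, float)
    if v.size < 100:
        raise ValidationError("a 95% BCa interval needs at least 100 replicates")
    if np.all(v == v[0]):
        return float(v[0]), float(v[0])
    if z0 is None:
        prop = np.mean(v < point)
        prop = min(max(prop, 1 / (2 * v.size)), 1 - 1 / (2 * v.size))
        z0 = stats.norm.ppf(prop)
    if accel is None:
        jk = np.asarray(jackknife, float)
        d = jk.mean() - jk
        denom = (d**2).sum() ** 1.5
        accel = float((d**3).sum() / (6 * denom)) if denom > 0 else 0.0
    alpha = (1 - level) / 2
    out = []
    for a_lvl in (alpha, 1 - alpha):
        z = stats.norm.ppf(a_lvl)
        adj = z0 + (z0 + z) / (1 - accel * (z0 + z))
        out.append(float(np.quantile(v, np.clip(stats.norm.cdf(adj), 0, 1))))
    lo, hi = min(out), max(out)
    return lo, hi


# ---------------------------------------------------------------------------
# pain outcome: exchangeable-covariance repeated-measures GLS


def fit_pain_mixed_model(long_df: pd.DataFrame, covariates=("baseline_pain_nrs",),
                         id_col: str = "id", visit_col: str = "visit",
                         outcome_col: str = "pain", arm_col: str = "arm",
                         visit_effects: bool = True):
    """Arm effect on pain by visit under compound-symmetry covariance.

    The model is outcome ~ arm * visit + covariates with within-person
    covariance σ²[(1−ρ)I + ρJ]; ρ is estimated by the method of moments from
    OLS residual cross-products and clipped into its valid range with a
    warning if necessary.  Returns a dict visit -> (effect, se) plus rho and
    sigma2.  With ρ = 0 the estimates equal OLS.
    """
    df = long_df.dropna(subset=[outcome_col]).reset_index(drop=True)
    visits = sorted(df[visit_col].unique())
    if len(visits) < 1:
        raise ValidationError("no pain observations")
    cols = {"const": np.ones(len(df)),
            "arm": (df[arm_col] == "intervention").astype(float).to_numpy()}
    if visit_effects:
        for v in visits[1:]:
            ind = (df[visit_col] == v).astype(float).to_numpy()
            cols[f"visit_{v}"] = ind
            cols[f"arm:visit_{v}"] = ind * cols["arm"]
    for c in covariates:
        x = df[c]
        if x.dtype == object:
            x = (x == "F").astype(float)
        cols[c] = np.asarray(x, float)
    names = list(cols)
    X = np.column_stack(list(cols.values()))
    y = df[outcome_col].to_numpy(float)
    _check_rank(X, names)

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (len(y) - X.shape[1])

    # moment estimate of the common within-person correlation
    cross, npairs = 0.0, 0
    for _, g in pd.Series(resid).groupby(df[id_col].to_numpy()):
        r = g.to_numpy()
        t = r.size
        if t > 1:
            cross += (r.sum() ** 2 - (r**2).sum()) / 2
            npairs += t * (t - 1) // 2
    rho = cross / (npairs * sigma2) if npairs else 0.0
    t_max = max(df.groupby(id_col).size())
    lo, hi = -1 / (t_max - 1) + 1e-6 if t_max > 1 else -1 + 1e-6, 1 - 1e-6
    if not lo <= rho <= hi:
        warnings.warn(f"exchangeable correlation estimate {rho:.3f} outside "
                      f"({lo:.3f}, {hi:.3f}); clipped", stacklevel=2)
        rho = float(np.clip(rho, lo, hi))

    # GLS by per-person whitening: inverse of σ²[(1−ρ)I + ρJ] is closed form
    XtWX = np.zeros((X.shape[1], X.shape[1]))
    XtWy = np.zeros(X.shape[1])
    for _, g in df.groupby(id_col, sort=False):
        ix = g.index.to_numpy()
        Xi, yi = X[ix], y[ix]
        t = len(ix)
        Vinv = (np.eye(t) - rho / (1 + (t - 1) * rho) * np.ones((t, t))) / (1 - rho)
        XtWX += Xi.T @ Vinv @ Xi
        XtWy += Xi.T @ Vinv @ yi
    beta_gls = np.linalg.solve(XtWX, XtWy)
    cov = sigma2 * np.linalg.inv(XtWX)

    j_arm = names.index("arm")
    effects = {}
    for v in visits:
        contrast = np.zeros(len(names))
        contrast[j_arm] = 1.0
        if f"arm:visit_{v}" in names:
            contrast[names.index(f"arm:visit_{v}")] = 1.0
        eff = float(contrast @ beta_gls)
        se = float(np.sqrt(contrast @ cov @ contrast))
        effects[v] = (eff, se)
    return {"effects_by_visit": effects, "rho": float(rho), "sigma2": sigma2,
            "coefficients": dict(zip(names, beta_gls))}
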