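"""Multiple imputation by chained equations with predictive mean matching.

The base-case intention-to-treat analysis fills missing cost and utility
components under a missing-at-random assumption.  Each imputable variable is
regressed in turn on the imputation-model covariates (baseline hand-pain
severity, concomitant analgesic use, average grip strength, BMI, age, gender,
baseline costs, baseline utility) plus the current fill-ins of the other
imputable variables; predictive mean matching (PMM) then replaces each
missing value by the observed value of one of the k nearest donors in
predicted-mean space, so imputations are always actually-observed values and
respect bounds and skewness by construction.

Parameter uncertainty is propagated by drawing the regression coefficients
from their estimated sampling distribution before predicting the missing
cases (type-1 matching); continuous variables use a linear model and binary
variables a logistic link.  The m completed datasets are combined downstream
with Rubin's rules (Barnard–Rubin small-sample degrees of freedom).

m, the number of chained-equation cycles and the donor-pool size k are not
dictated by the method; the defaults (m = 20, 10 cycles, k = 5) follow common
practice and are configuration-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .schema import ConfigurationError, ValidationError

__all__ = ["ImputationSpec", "mice_pmm", "pool_rubin", "DEFAULT_MODEL_COVARIATES"]

DEFAULT_MODEL_COVARIATES = (
    "baseline_pain_nrs", "concomitant_analgesic", "grip_strength",
    "bmi", "age", "gender", "cost_baseline", "u0",
)


@dataclass
class ImputationSpec:
    m: int = 20
    iterations: int = 10
    pmm_donors: int = 5
    model_covariates: tuple = DEFAULT_MODEL_COVARIATES
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ConfigurationError("number of imputations m must be >= 2")
        if self.pmm_donors < 1:
            raise ConfigurationError("PMM donor-pool size k must be >= 1")
        if not self.model_covariates:
            raise ConfigurationError("imputation model needs at least one covariate")
        if self.iterations < 1:
            raise ConfigurationError("need at least one chained-equation cycle")


def _design(df: pd.DataFrame, cols) -> np.ndarray:
    """Numeric design matrix with intercept; 'gender' is encoded F=1/M=0."""
    parts = [np.ones(len(df))]
    for c in cols:
        x = df[c]
        if x.dtype == object:
            x = (x == "F").astype(float)
        parts.append(np.asarray(x, dtype=float))
    return np.column_stack(parts)


def _draw_beta(X: np.ndarray, y: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit plus a posterior-style draw of the coefficients.

    Returns (beta_hat, beta_draw).  Uses ridge-stabilised normal equations so
    nearly-collinear fill-ins cannot abort a chain mid-cycle.
    """
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(XtX)
    cov = (cov + cov.T) / 2
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        L = np.zeros((p, p))
    beta_draw = beta_hat + L @ rng.standard_normal(p)
    if not np.all(np.isfinite(beta_draw)):
        raise ValidationError("chained-equation model diverged (non-finite coefficients)")
    return beta_hat, beta_draw


def _logit_predict(X: np.ndarray, y: np.ndarray, X_new: np.ndarray, rng):
    """Logistic fit (Newton with ridge) returning observed and drawn predictions."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(25):
        eta = X @ beta
        mu = special.expit(eta)
        W = mu * (1 - mu) + 1e-6
        H = (X * W[:, None]).T @ X + 1e-6 * np.eye(p)
        g = X.T @ (y - mu)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    cov = np.linalg.inv(H)
    L = np.linalg.cholesky((cov + cov.T) / 2 + 1e-12 * np.eye(p))
    beta_draw = beta + L @ rng.standard_normal(p)
    return special.expit(X @ beta), special.expit(X_new @ beta_draw)


def _pmm_draw(pred_obs: np.ndarray, y_obs: np.ndarray, pred_mis: np.ndarray,
              k: int, rng) -> np.ndarray:
    """For each missing case, draw one of the k nearest observed donors.

    Donor search is done on the sorted observed predictions: the k nearest
    donors lie inside a 2k-wide window around the insertion point.  Ties among
    equidistant donors at the pool boundary are broken uniformly at random via
    an infinitesimal distance jitter.
    """
    n_obs = y_obs.size
    k = min(k, n_obs)
    order = np.argsort(pred_obs, kind="stable")
    so, yo = pred_obs[order], y_obs[order]
    w = min(2 * k, n_obs)
    pos = np.searchsorted(so, pred_mis)
    start = np.clip(pos - k, 0, n_obs - w)
    idx = start[:, None] + np.arange(w)
    d = np.abs(so[idx] - pred_mis[:, None])
    scale = max(float(so[-1] - so[0]), 1.0)
    d = d + rng.random(d.shape) * (1e-10 * scale)
    pool = np.argpartition(d, k - 1, axis=1)[:, :k]
    pick = pool[np.arange(pred_mis.size), rng.integers(0, k, size=pred_mis.size)]
    return yo[idx[np.arange(pred_mis.size), pick]]


def _validate_imputable(df: pd.DataFrame, impute_cols, spec: ImputationSpec) -> list:
    impute_cols = [c for c in impute_cols if df[c].isna().any()]
    for c in impute_cols:
        col = df[c]
        if not col.notna().any():
            raise ValidationError(f"variable '{c}' is 100% missing: no PMM donors exist")
        if col.dtype == object:
            raise ValidationError(f"imputable variable '{c}' is non-numeric")
    missing_cov = [c for c in spec.model_covariates if c not in df.columns]
    if missing_cov:
        raise ConfigurationError(f"imputation covariates absent from data: {missing_cov}")
    fully_obs = [c for c in spec.model_covariates if df[c].notna().all()]
    if not fully_obs:
        raise ValidationError("imputation model needs at least one fully observed covariate")
    return impute_cols


def _impute_once(df: pd.DataFrame, impute_cols, spec: ImputationSpec,
                 rng) -> pd.DataFrame:
    """One stochastic chained-equation pass producing a single completed copy.

    Used m times by :func:`mice_pmm` and once inside each bootstrap replicate
    under the boot-then-impute strategy.
    """
    impute_cols = _validate_imputable(df, impute_cols, spec)
    if not impute_cols:
        return df.copy()
    na_mask = {c: df[c].isna().to_numpy() for c in impute_cols}
    work = df.copy()
    # initial fill: random draws from each variable's observed values
    for c in impute_cols:
        obs = work[c].dropna().to_numpy()
        work.loc[na_mask[c], c] = rng.choice(obs, size=int(na_mask[c].sum()))
    for _cycle in range(spec.iterations):
        for c in impute_cols:
            others = [o for o in impute_cols if o != c]
            preds = [p for p in spec.model_covariates if p != c] + others
            X = _design(work, preds)
            obs = ~na_mask[c]
            y_obs = work.loc[obs, c].to_numpy(float)
            uniq = np.unique(y_obs)
            if uniq.size == 2 and set(uniq) <= {0.0, 1.0}:
                pred_obs, pred_mis = _logit_predict(X[obs], y_obs, X[na_mask[c]], rng)
            else:
                beta_hat, beta_draw = _draw_beta(X[obs], y_obs, rng)
                pred_obs = X[obs] @ beta_hat
                pred_mis = X[na_mask[c]] @ beta_draw
            if not (np.all(np.isfinite(pred_obs)) and np.all(np.isfinite(pred_mis))):
                raise ValidationError(f"chained equation for '{c}' diverged")
            work.loc[na_mask[c], c] = _pmm_draw(pred_obs, y_obs, pred_mis,
                                                spec.pmm_donors, rng)
    return work


def mice_pmm(df: pd.DataFrame, impute_cols, spec: ImputationSpec,
             rng=None) -> list[pd.DataFrame]:
    """m completed copies of `df`, identical to it at every observed cell.

    `impute_cols` are the (numeric) variables whose missing cells are filled;
    the spec's model covariates must be columns of `df`.  A variable that is
    100% missing has no donors and is an error.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    _validate_imputable(df, impute_cols, spec)
    return [_impute_once(df, impute_cols, spec, rng) for _ in range(spec.m)]


def pool_rubin(estimates, variances, dfcom: float | None = None):
    """Rubin's rules for m per-imputation (estimate, variance) pairs.

    Returns (pooled estimate, total variance, degrees of freedom).  Total
    variance is within-imputation mean plus (1 + 1/m) times the
    between-imputation variance; df follows Barnard–Rubin when a
    complete-data df is supplied, else the classic large-sample formula.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValidationError("estimates and variances have mismatched lengths")
    m = q.size
    if m < 2:
        raise ValidationError("pooling needs m >= 2 estimates")
    qbar = q.mean()
    ubar = u.mean()
    b = q.var(ddof=1)
    t = ubar + (1 + 1 / m) * b
    if b == 0 or t == 0:
        return float(qbar), float(t), float("inf")
    lam = (1 + 1 / m) * b / t
    df_large = (m - 1) / lam**2
    if dfcom is None:
        return float(qbar), float(t), float(df_large)
    df_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
    df = 1 / (1 / df_large + 1 / df_obs)
    return float(qbar), float(t), float(df)
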