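"""Decision outputs: ICER with quadrant semantics, net benefit, CE plane, CEAC.

The incremental cost-effectiveness ratio ΔC/ΔE only carries its usual
"cost per QALY gained" meaning in the north-east quadrant of the
cost-effectiveness plane.  The quadrants (ΔE on x, ΔC on y):

* NE (ΔC ≥ 0, ΔE ≥ 0) — more costly, more effective: ICER = cost per QALY
  gained, compared against the threshold λ;
* SE (ΔC < 0, ΔE ≥ 0) — cheaper and at least as effective: dominant, no
  ratio needed;
* NW (ΔC ≥ 0, ΔE < 0) — more costly, less effective: dominated;
* SW (ΔC < 0, ΔE < 0) — cheaper but less effective: the ratio is reported as
  a positive "cost saved per QALY lost", and under symmetric preferences for
  health gains and losses the intervention is cost-effective only when that
  saving exceeds λ — equivalently when net monetary benefit λ·ΔE − ΔC > 0.

Boundary convention: ΔE = 0 (or ΔC = 0) counts as a gain (cost increase), so
every replicate lands in exactly one quadrant; a net benefit of exactly zero
counts as not cost-effective.  Both choices are deterministic and
conservative.

"Net benefit" here is the monetary form NMB = λ·ΔE − ΔC (the form whose units
match published £-denominated tables); the QALY-denominated variant
ΔE − ΔC/λ is exposed separately as ``net_health_benefit``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import BootstrapCloud
from .schema import ValidationError

__all__ = ["Threshold", "IcerResult", "icer", "net_benefit", "net_health_benefit",
           "ceac", "ce_plane_export", "default_lambda_grid", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = (20_000.0, 30_000.0)  # NICE range, £/QALY


@dataclass(frozen=True)
class Threshold:
    lam: float

    def __post_init__(self):
        if self.lam <= 0:
            raise ValidationError(f"threshold must be positive, got {self.lam}")


def default_lambda_grid() -> np.ndarray:
    """£0–50,000 in £500 steps (0 excluded from net-benefit ratios downstream)."""
    return np.arange(0.0, 50_000.0 + 1, 500.0)


def _quadrant(delta_cost: float, delta_qaly: float) -> str:
    if delta_qaly >= 0:
        return "NE" if delta_cost >= 0 else "SE"
    return "NW" if delta_cost >= 0 else "SW"


@dataclass(frozen=True)
class IcerResult:
    value: float | None
    quadrant: str
    interpretation: str
    delta_cost: float
    delta_qaly: float


def icer(delta_cost: float, delta_qaly: float) -> IcerResult:
    """ΔC/ΔE with quadrant classification.

    Degenerate cases are flagged states, never exceptions: zero ΔE yields no
    ratio; SE is dominant and NW dominated without a ratio; the SW ratio is
    reported positive, as cost saved per QALY lost.
    """
    q = _quadrant(delta_cost, delta_qaly)
    if delta_qaly == 0:
        return IcerResult(None, q, "undefined (zero effect)", delta_cost, delta_qaly)
    if q == "SE":
        return IcerResult(None, q, "dominant", delta_cost, delta_qaly)
    if q == "NW":
        return IcerResult(None, q, "dominated", delta_cost, delta_qaly)
    value = delta_cost / delta_qaly
    interp = "cost per QALY gained" if q == "NE" else "cost saved per QALY lost"
    return IcerResult(float(value), q, interp, delta_cost, delta_qaly)


def net_benefit(delta_cost, delta_qaly, threshold) -> float:
    """Net monetary benefit λ·ΔE − ΔC (£); positive means cost-effective at λ."""
    lam = threshold.lam if isinstance(threshold, Threshold) else float(threshold)
    if lam <= 0:
        raise ValidationError(f"threshold must be positive, got {lam}")
    return lam * np.asarray(delta_qaly, float) - np.asarray(delta_cost, float)


def net_health_benefit(delta_cost, delta_qaly, threshold) -> float:
    """QALY-denominated net benefit ΔE − ΔC/λ."""
    lam = threshold.lam if isinstance(threshold, Threshold) else float(threshold)
    if lam <= 0:
        raise ValidationError(f"threshold must be positive, got {lam}")
    return np.asarray(delta_qaly, float) - np.asarray(delta_cost, float) / lam


def ceac(cloud: BootstrapCloud, lambda_grid=None) -> pd.DataFrame:
    """Probability cost-effective across thresholds.

    At each λ the probability is the fraction of bootstrap replicates with
    strictly positive net monetary benefit; exactly zero counts as not
    cost-effective.
    """
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size == 0:
        raise ValidationError("empty threshold grid")
    nb = grid[:, None] * cloud.delta_qaly[None, :] - cloud.delta_cost[None, :]
    prob = (nb > 0).mean(axis=1)
    return pd.DataFrame({"lambda": grid, "probability": prob})


def ce_plane_export(cloud: BootstrapCloud):
    """Replicate scatter table plus quadrant shares (closed lower boundary).

    Returns (DataFrame with replicate/delta_cost/delta_qaly/quadrant, shares
    dict summing exactly to 1).
    """
    df = cloud.to_frame()
    de, dc = cloud.delta_qaly, cloud.delta_cost
    quad = np.where(de >= 0, np.where(dc >= 0, "NE", "SE"),
                    np.where(dc >= 0, "NW", "SW"))
    df["quadrant"] = quad
    shares = {q: float(np.mean(quad == q)) for q in ("NE", "SE", "SW", "NW")}
    return df, shares
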