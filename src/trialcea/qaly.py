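"""QALYs from utility trajectories by trapezoid area under the curve.

Utilities are measured at the protocol-scheduled visits 0, 6 and 12 months
(0, 0.5 and 1.0 years); the quality-adjusted life years accrued over the
12-month horizon are the area under the piecewise-linear utility curve:

    QALY = 0.5 * (u0 + u6) / 2  +  0.5 * (u6 + u12) / 2
         = 0.25 * u0 + 0.5 * u6 + 0.25 * u12

Baseline-utility adjustment is NOT applied here: it enters downstream as a
regression covariate in the estimation stage, which is the standard way to
correct for chance baseline imbalance in trial-based QALY comparisons.
Missing utilities propagate (any missing visit makes the QALY missing);
in the base-case pipeline imputation happens before this computation.

Also houses the pain-score change used by the cost-effectiveness analysis:
hand pain on a 0–10 numerical rating scale (NRS), change = 6-month minus
baseline, negative meaning pain reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import ValidationError

VISIT_YEARS = (0.0, 0.5, 1.0)
_WEIGHTS = np.array([0.25, 0.5, 0.25])

__all__ = ["UtilityTrajectory", "qaly_auc", "qaly_auc_frame", "pain_change"]


@dataclass(frozen=True)
class UtilityTrajectory:
    """Utilities at 0, 6 and 12 months; NaN marks a missing measurement."""

    u0: float
    u6: float
    u12: float

    def as_array(self) -> np.ndarray:
        return np.array([self.u0, self.u6, self.u12], dtype=float)


def qaly_auc(traj) -> float:
    """Trapezoid-rule QALYs over one year; NaN if any utility is missing."""
    u = traj.as_array() if isinstance(traj, UtilityTrajectory) else np.asarray(traj, float)
    if u.shape != (3,):
        raise ValidationError(f"expected utilities at 3 visits, got shape {u.shape}")
    if np.isnan(u).any():
        return float("nan")
    return float(_WEIGHTS @ u)


def qaly_auc_frame(u0, u6, u12) -> np.ndarray:
    """Vectorised trapezoid QALYs; rows with any missing utility give NaN."""
    u = np.column_stack([np.asarray(u0, float), np.asarray(u6, float),
                         np.asarray(u12, float)])
    return u @ _WEIGHTS


def pain_change(nrs6: float, nrs0: float) -> float:
    """Change in hand-pain NRS, 6 months minus baseline.

    Scores must lie in 0..10.  Negative values denote pain reduction; a
    positive between-arm contrast on this scale means the intervention arm
    reported worse pain, in which case a cost-per-pain-reduction ratio is
    not meaningful (flagged by the decision stage, not here).
    """
    for label, v in (("nrs6", nrs6), ("nrs0", nrs0)):
        if np.isnan(v):
            return float("nan")
        if not 0 <= v <= 10:
            raise ValidationError(f"{label}={v} outside the 0..10 pain NRS range")
    return float(nrs6) - float(nrs0)
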