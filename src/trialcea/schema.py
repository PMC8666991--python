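"""Canonical participant-level dataset layout.

One row per participant, wide format. Missing values are empty fields in CSV
(NaN in memory). All stage boundaries in the package exchange data in this
layout, so the column-name vocabulary lives here.
"""

from __future__ import annotations

# EQ-5D-5L dimensions, in instrument order
EQ5D_DIMS = ("mo", "sc", "ua", "pd", "ad")
EQ5D_DIM_NAMES = {
    "mo": "mobility",
    "sc": "self_care",
    "ua": "usual_activities",
    "pd": "pain_discomfort",
    "ad": "anxiety_depression",
}

# Questionnaire visits, months from randomisation
VISITS = (0, 6, 12)
# Investigator medication-form intervals, months
MED_INTERVALS = (3, 6, 9, 12)

ARMS = ("intervention", "control")

# Healthcare resource-use items (unit-cost table keys)
RESOURCE_ITEMS = (
    "hospital_outpatient",
    "a_and_e",
    "other_outpatient",
    "gp_surgery",
    "gp_home",
    "nurse_surgery",
    "other_primary_care",
    "physiotherapist",
    "occupational_therapist",
    "other_community_care",
)

# Medication categories costed at category-average prices
MEDICATION_CATEGORIES = (
    "oral_opioid",
    "oral_nsaid",
    "topical_nsaid",
    "antidepressant_neuropathic",
    "other_analgesic",
)

# Out-of-pocket expense kinds (societal perspective)
EXPENSE_KINDS = ("otc", "childcare", "travel")

BASELINE_COVARIATES = (
    "age",
    "gender",
    "bmi",
    "baseline_pain_nrs",
    "grip_strength",
    "concomitant_analgesic",
)


def eq5d_col(dim: str, visit: int) -> str:
    return f"eq5d_{dim}_{visit}m"


def vas_col(visit: int) -> str:
    return f"vas_{visit}m"


def resource_col(item: str, visit: int) -> str:
    return f"ru_{item}_{visit}m"


def med_col(category: str, interval: int) -> str:
    return f"med_{category}_{interval}m"


def expense_col(kind: str, visit: int) -> str:
    return f"exp_{kind}_{visit}m"


def pain_col(visit: int) -> str:
    return "baseline_pain_nrs" if visit == 0 else f"pain_nrs_{visit}m"


def eq5d_cols(visit: int) -> list[str]:
    return [eq5d_col(d, visit) for d in EQ5D_DIMS]


def resource_cols(visit: int) -> list[str]:
    return [resource_col(i, visit) for i in RESOURCE_ITEMS]


def expense_cols(visit: int) -> list[str]:
    return [expense_col(k, visit) for k in EXPENSE_KINDS]


def med_cols() -> list[str]:
    return [med_col(c, i) for c in MEDICATION_CATEGORIES for i in MED_INTERVALS]


def all_columns() -> list[str]:
    """Full canonical column order."""
    cols = ["id", "arm"]
    cols += list(BASELINE_COVARIATES)
    for v in VISITS:
        cols += eq5d_cols(v)
        cols.append(vas_col(v))
    cols += [pain_col(6), pain_col(12)]
    for v in VISITS:
        cols += resource_cols(v)
    cols += ["hcq_dose_mg", "hcq_days"]
    cols += med_cols()
    for v in VISITS:
        cols += expense_cols(v)
    return cols


class ValidationError(ValueError):
    """Raised when input data or configuration violates the documented schema."""


class ConfigurationError(ValueError):
    """Raised when a configuration object is internally inconsistent."""
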