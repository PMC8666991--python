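"""Per-participant 12-month costs under NHS/PSS and societal perspectives.

Cost components:

* healthcare resource use — self-reported counts per item (outpatient, A&E,
  GP, nurse, therapist, ... visits) multiplied by unit costs from national
  costing sources (2015 UK £; no discounting over the one-year horizon);
* study drug — hydroxychloroquine (HCQ) sulfate costed from the 200 mg
  60-tablet pack price (£5.15 default), daily dose 200/300/400 mg where
  300 mg is alternating 200/400 (1.5 tablets/day on average), truncated at
  the recorded stop/withdrawal day.  Placebo tablets are a research cost and
  contribute £0;
* concomitant medications — investigator-recorded uses at the 3/6/9/12-month
  forms, costed at category-average prices rather than per-product
  micro-costing;
* personal expenses — participant-stated £ for over-the-counter medication,
  childcare and travel; counted only under the societal perspective.

The trial-period total sums the 6- and 12-month follow-up components; the
baseline questionnaire covers pre-randomisation use and enters the analysis
only as the baseline-cost covariate.  Item-level missing counts make that
visit's resource cost missing (not zero) — fill-in is the imputation stage's
decision, and available-case descriptives remain item-wise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .schema import (ConfigurationError, RESOURCE_ITEMS, MEDICATION_CATEGORIES,
                     MED_INTERVALS, EXPENSE_KINDS, ValidationError)

_DATA = Path(__file__).parent / "data"

__all__ = [
    "UnitCostTable", "DrugCostConfig", "MedicationCategoryCosts",
    "CostBreakdown", "cost_resources", "cost_hcq", "cost_medications",
    "total_cost", "compute_cost_components",
]


@dataclass(frozen=True)
class UnitCostTable:
    """Unit cost (£) per healthcare resource item."""

    costs: dict = field(repr=False)
    descriptions: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for item, c in self.costs.items():
            if c < 0:
                raise ConfigurationError(f"negative unit cost for '{item}'")

    def __getitem__(self, item: str) -> float:
        try:
            return self.costs[item]
        except KeyError:
            raise ConfigurationError(f"no unit cost for resource item '{item}'") from None

    @classmethod
    def load(cls, path=None) -> "UnitCostTable":
        path = Path(path) if path else _DATA / "unit_costs.csv"
        costs, desc = {}, {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                costs[row["item"]] = float(row["unit_cost"])
                desc[row["item"]] = row.get("unit_description", "")
        return cls(costs=costs, descriptions=desc)


@dataclass(frozen=True)
class DrugCostConfig:
    """HCQ acquisition-cost parameters (British National Formulary pack price)."""

    pack_price: float = 5.15
    tablets_per_pack: int = 60
    tablet_strength_mg: int = 200

    def __post_init__(self):
        if self.pack_price <= 0 or self.tablets_per_pack <= 0 or self.tablet_strength_mg <= 0:
            raise ConfigurationError("drug cost parameters must all be positive")

    @property
    def tablet_price(self) -> float:
        return self.pack_price / self.tablets_per_pack


@dataclass(frozen=True)
class MedicationCategoryCosts:
    """Average cost (£) per recorded use-interval, by medication category.

    The shipped defaults are uncalibrated placeholders: the category averages
    used in the trial costing were derived from its own prescription records
    and are not published.  Override with a `category,avg_cost` CSV for any
    substantive re-costing.
    """

    costs: dict = field(repr=False)
    calibrated: bool = False

    def __post_init__(self):
        for cat, c in self.costs.items():
            if c < 0:
                raise ConfigurationError(f"negative category cost for '{cat}'")

    def __getitem__(self, category: str) -> float:
        try:
            return self.costs[category]
        except KeyError:
            raise ConfigurationError(
                f"unknown medication category '{category}'; known: {sorted(self.costs)}") from None

    @classmethod
    def load(cls, path=None) -> "MedicationCategoryCosts":
        calibrated = path is not None
        path = Path(path) if path else _DATA / "medication_category_costs.csv"
        with open(path, newline="", encoding="utf-8") as fh:
            costs = {row["category"]: float(row["avg_cost"]) for row in csv.DictReader(fh)}
        return cls(costs=costs, calibrated=calibrated)


@dataclass
class CostBreakdown:
    """One participant's cost components (£) over the trial period."""

    healthcare: dict            # item -> £ (may contain NaN)
    drug: float
    medications: float
    societal_extras: float      # OTC + childcare + travel

    @property
    def nhs_pss(self) -> float:
        return float(sum(self.healthcare.values()) + self.drug + self.medications)

    @property
    def societal(self) -> float:
        return self.nhs_pss + self.societal_extras


def cost_resources(counts, table: UnitCostTable) -> dict:
    """Item-wise cost = count × unit cost; missing count -> missing item cost."""
    out = {}
    for item, n in dict(counts).items():
        unit = table[item]
        if n is None or (isinstance(n, float) and np.isnan(n)):
            out[item] = float("nan")
            continue
        if n < 0 or float(n) != int(n):
            raise ValidationError(f"resource count for '{item}' must be a nonnegative integer, got {n!r}")
        out[item] = float(n) * unit
    return out


def cost_hcq(dose_mg: int, days: int, cfg: DrugCostConfig = DrugCostConfig()) -> float:
    """HCQ cost for `days` of treatment at a constant daily dose.

    300 mg is taken as alternating 200/400 mg, i.e. 1.5 tablets/day average.
    """
    if dose_mg not in (200, 300, 400):
        raise ValidationError(f"HCQ daily dose must be 200, 300 or 400 mg, got {dose_mg}")
    if not 0 <= days <= 365:
        raise ValidationError(f"treatment days must be in 0..365, got {days}")
    tablets_per_day = dose_mg / cfg.tablet_strength_mg
    return tablets_per_day * cfg.tablet_price * days


def cost_medications(category_uses, cat_costs: MedicationCategoryCosts) -> float:
    """Sum of category-average costs over recorded use-intervals.

    `category_uses` is either an iterable of category labels (one per recorded
    use) or a mapping category -> number of use-intervals.
    """
    if isinstance(category_uses, dict):
        pairs = category_uses.items()
    else:
        labels = list(category_uses)
        pairs = ((lab, labels.count(lab)) for lab in dict.fromkeys(labels))
    total = 0.0
    for cat, n in pairs:
        if n < 0:
            raise ValidationError(f"negative use count for category '{cat}'")
        total += cat_costs[cat] * n
    return total


def total_cost(breakdown: CostBreakdown, perspective: str, arm: str | None = None) -> float:
    """Perspective total; NHS/PSS excludes personal expenses.

    Passing the participant's arm enables the placebo rule check: a control
    participant with nonzero study-drug cost is a data error.
    """
    if arm == "control" and breakdown.drug != 0:
        raise ValidationError("control-arm participant has nonzero study-drug cost")
    if perspective == "nhs_pss":
        return breakdown.nhs_pss
    if perspective == "societal":
        return breakdown.societal
    raise ConfigurationError(f"unknown perspective '{perspective}'")


# ---------------------------------------------------------------------------
# Frame-level costing for the pipeline


def compute_cost_components(df: pd.DataFrame,
                            unit_costs: UnitCostTable | None = None,
                            drug_cfg: DrugCostConfig = DrugCostConfig(),
                            med_costs: MedicationCategoryCosts | None = None) -> pd.DataFrame:
    """Per-participant cost components for every visit, as new columns.

    Adds, per visit v in {0, 6, 12}: ``cost_resources_{v}m`` (NaN when any
    item count at that visit is missing) and ``cost_expenses_{v}m``; plus
    ``cost_drug`` (0 for controls) and ``cost_medications`` (investigator
    forms, treated as fully observed).
    """
    unit_costs = unit_costs or UnitCostTable.load()
    med_costs = med_costs or MedicationCategoryCosts.load()
    out = df.copy()
    unit_vec = np.array([unit_costs[i] for i in RESOURCE_ITEMS])
    for v in schema.VISITS:
        counts = df[schema.resource_cols(v)].to_numpy(float)
        if np.nanmin(counts, initial=0) < 0:
            raise ValidationError("negative resource count")
        out[f"cost_resources_{v}m"] = counts @ unit_vec  # NaN propagates item-wise
        exp = df[schema.expense_cols(v)].to_numpy(float)
        out[f"cost_expenses_{v}m"] = exp.sum(axis=1)

    cat_vec = np.array([med_costs[c] for c in MEDICATION_CATEGORIES])
    med_counts = (df[schema.med_cols()].to_numpy(float)
                  .reshape(len(df), len(MEDICATION_CATEGORIES), len(MED_INTERVALS)))
    out["cost_medications"] = med_counts.sum(axis=2) @ cat_vec

    drug = np.zeros(len(df))
    on_drug = df["arm"].to_numpy() == "intervention"
    for i in np.flatnonzero(on_drug):
        dose, days = df["hcq_dose_mg"].iat[i], df["hcq_days"].iat[i]
        if np.isnan(dose) or np.isnan(days):
            drug[i] = 0.0
        else:
            drug[i] = cost_hcq(int(dose), int(days), drug_cfg)
    ctrl_drug = df.loc[~on_drug, "hcq_dose_mg"]
    if ctrl_drug.notna().any():
        raise ValidationError("control-arm participant has HCQ exposure recorded")
    out["cost_drug"] = drug

    # trial-period totals (6m + 12m follow-up components)
    out["cost_nhs_pss"] = (out["cost_resources_6m"] + out["cost_resources_12m"]
                           + out["cost_drug"] + out["cost_medications"])
    out["cost_societal"] = (out["cost_nhs_pss"] + out["cost_expenses_6m"]
                            + out["cost_expenses_12m"])
    out["cost_baseline"] = out["cost_resources_0m"]
    return out
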