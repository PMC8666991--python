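"""EQ-5D-5L utility scoring against a pluggable tariff (value set).

The EQ-5D-5L describes a health state by five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each at one of five
levels (1 = no problems ... 5 = extreme problems / unable to).  A tariff maps
each of the 5^5 = 3125 states to a societal utility anchored at 1.0 for full
health (state 11111) and 0 for death; negative utilities denote states valued
worse than death.  Published value sets (e.g. the 5L-to-3L crosswalk) are one
such tariff; the scoring engine is agnostic to which table is plugged in.

Two tariff CSV dialects are supported (UTF-8, header required):

* exhaustive — ``state,utility`` with ``state`` a 5-digit string, all 3125
  states present exactly once;
* coefficient — ``term,value`` rows defining an additive decrement model:
  utility = 1.0 − Σ decrements.  Terms are ``<DIM><level>`` (DIM in
  MO/SC/UA/PD/AD, level 2–5), giving the decrement applied when that dimension
  is at that level, plus the optional interaction term ``N45`` subtracted once
  if any dimension is at level 4 or 5.  An optional ``anchor`` row must be 1.0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .schema import EQ5D_DIMS, EQ5D_DIM_NAMES, ValidationError

N_STATES = 5**5
_DIM_CODES = ("MO", "SC", "UA", "PD", "AD")

__all__ = ["TariffTable", "score_state", "load_tariff", "default_tariff_path",
           "state_index", "all_states"]


def state_index(levels) -> int:
    """Index of a 5-level state in the fixed enumeration (11111 -> 0)."""
    idx = 0
    for lv in levels:
        idx = idx * 5 + (int(lv) - 1)
    return idx


def all_states() -> np.ndarray:
    """(3125, 5) array of every state's levels, in enumeration order."""
    grids = np.meshgrid(*[np.arange(1, 6)] * 5, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


@dataclass(frozen=True)
class TariffTable:
    """Utility lookup for all 3125 EQ-5D-5L states.

    ``values[state_index(levels)]`` is the utility of that state.  The anchor
    invariant (state 11111 scores exactly 1.0) and the utility ceiling
    (no state above 1.0) are enforced at construction.
    """

    name: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_STATES,):
            raise ValidationError(
                f"tariff '{self.name}': expected {N_STATES} utilities, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"tariff '{self.name}': non-finite utilities")
        if v[0] != 1.0:
            raise ValidationError(
                f"tariff '{self.name}': state 11111 must score exactly 1.0, got {v[0]}")
        if np.any(v > 1.0):
            raise ValidationError(f"tariff '{self.name}': utilities above 1.0")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_coefficients(cls, name: str, coeffs: dict) -> "TariffTable":
        """Build from an additive decrement model (see module docstring)."""
        coeffs = dict(coeffs)
        anchor = coeffs.pop("anchor", 1.0)
        if anchor != 1.0:
            raise ValidationError(f"tariff '{name}': anchor must be 1.0, got {anchor}")
        n45 = float(coeffs.pop("N45", 0.0))
        dec = np.zeros((5, 6))  # dec[dim, level]
        for term, value in coeffs.items():
            code, lvl = term[:2].upper(), term[2:]
            if code not in _DIM_CODES or lvl not in {"2", "3", "4", "5"}:
                raise ValidationError(f"tariff '{name}': unknown term '{term}'")
            dec[_DIM_CODES.index(code), int(lvl)] = float(value)
        states = all_states()
        util = 1.0 - dec[np.arange(5)[None, :], states].sum(axis=1)
        util -= n45 * np.any(states >= 4, axis=1)
        return cls(name=name, values=util)

    def utility_range(self) -> tuple[float, float]:
        return float(self.values.min()), float(self.values.max())


def score_state(responses, tariff: TariffTable) -> float:
    """Utility of a single five-dimension response profile.

    Any missing dimension (None or NaN) makes the whole score missing (NaN):
    the instrument has no partial-scoring rule.  A level outside 1..5 is a
    validation error naming the offending dimension.
    """
    levels = []
    for dim, r in zip(EQ5D_DIMS, responses):
        if r is None or (isinstance(r, float) and np.isnan(r)):
            return float("nan")
        lv = float(r)
        if lv != int(lv) or not 1 <= lv <= 5:
            raise ValidationError(
                f"EQ-5D level for {EQ5D_DIM_NAMES[dim]} must be an integer in 1..5, got {r!r}")
        levels.append(int(lv))
    if len(levels) != 5:
        raise ValidationError(f"expected 5 dimension levels, got {len(levels)}")
    return float(tariff.values[state_index(levels)])


def score_states(levels: np.ndarray, tariff: TariffTable) -> np.ndarray:
    """Vectorised scoring of an (n, 5) level array; rows with any NaN -> NaN."""
    lv = np.asarray(levels, dtype=float)
    if lv.ndim != 2 or lv.shape[1] != 5:
        raise ValidationError(f"expected (n, 5) level array, got {lv.shape}")
    out = np.full(lv.shape[0], np.nan)
    complete = ~np.isnan(lv).any(axis=1)
    sub = lv[complete]
    if sub.size:
        if np.any((sub < 1) | (sub > 5) | (sub != np.round(sub))):
            bad = np.where((sub < 1) | (sub > 5) | (sub != np.round(sub)))
            dim = EQ5D_DIM_NAMES[EQ5D_DIMS[int(bad[1][0])]]
            raise ValidationError(f"EQ-5D level out of 1..5 for dimension {dim}")
        idx = np.zeros(sub.shape[0], dtype=int)
        for j in range(5):
            idx = idx * 5 + (sub[:, j].astype(int) - 1)
        out[complete] = tariff.values[idx]
    return out


def load_tariff(path) -> TariffTable:
    """Load a tariff CSV in either documented dialect.

    Errors (missing states, duplicates, anchor != 1.0) report row numbers.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValidationError(f"{path}: empty tariff file")
    header = [c.strip().lower() for c in rows[0]]
    name = path.stem
    if header == ["state", "utility"]:
        values = np.full(N_STATES, np.nan)
        seen_rows = {}
        for rno, row in enumerate(rows[1:], start=2):
            if not row or not "".join(row).strip():
                continue
            state, util = row[0].strip(), row[1]
            if len(state) != 5 or not state.isdigit() or "0" in state or any(c > "5" for c in state):
                raise ValidationError(f"{path}:{rno}: bad state '{state}'")
            idx = state_index(int(c) for c in state)
            if idx in seen_rows:
                raise ValidationError(
                    f"{path}:{rno}: duplicate state '{state}' (first at row {seen_rows[idx]})")
            seen_rows[idx] = rno
            values[idx] = float(util)
        missing = np.flatnonzero(np.isnan(values))
        if missing.size:
            st = "".join(str(d + 1) for d in np.unravel_index(missing[0], (5,) * 5))
            raise ValidationError(
                f"{path}: {missing.size} states unresolved (first missing: {st})")
        return TariffTable(name=name, values=values)
    if header == ["term", "value"]:
        coeffs = {}
        for rno, row in enumerate(rows[1:], start=2):
            if not row or not "".join(row).strip():
                continue
            term = row[0].strip()
            if term in coeffs:
                raise ValidationError(f"{path}:{rno}: duplicate term '{term}'")
            coeffs[term] = float(row[1])
        return TariffTable.from_coefficients(name, coeffs)
    raise ValidationError(
        f"{path}:1: header must be 'state,utility' or 'term,value', got {rows[0]}")


def default_tariff_path() -> Path:
    """Path of the shipped synthetic decrement-form tariff.

    This is a synthetic value set with the qualitative shape of published
    EQ-5D-5L tariffs (monotone decrements, severity interaction, a floor below
    zero); it is NOT a published value set.  Analyses of real data should plug
    in the licensed tariff for their jurisdiction via ``load_tariff``.
    """
    return Path(__file__).parent / "data" / "tariff_synthetic_decrement.csv"
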