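import numpy as np
import pandas as pd
import pytest

from trialcea.eq5d import TariffTable, load_tariff, default_tariff_path
from trialcea.synthetic import GeneratorConfig, generate_complete_trial, generate_trial


def linear_tariff() -> TariffTable:
    """Closed-form test tariff: utility = 1 - 0.05 * sum(level - 1)."""
    coeffs = {f"{code}{lvl}": 0.05 * (lvl - 1)
              for code in ("MO", "SC", "UA", "PD", "AD") for lvl in (2, 3, 4, 5)}
    return TariffTable.from_coefficients("linear_test", coeffs)


@pytest.fixture(scope="session")
def lin_tariff():
    return linear_tariff()


@pytest.fixture(scope="session")
def shipped_tariff():
    return load_tariff(default_tariff_path())


@pytest.fixture(scope="session")
def small_trial():
    """Default-condition synthetic trial (124/arm) with missingness."""
    return generate_trial(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def small_trial_complete():
    return generate_complete_trial(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def regression_frame():
    """Analysis-ready frame with known arm effects, no missingness."""
    rng = np.random.default_rng(5)
    n = 400
    df = pd.DataFrame({
        "id": [f"p{i}" for i in range(n)],
        "arm": np.repeat(["intervention", "control"], n // 2),
        "u0": rng.beta(4, 2.5, n),
        "cost_baseline": rng.gamma(2.0, 120.0, n),
        "baseline_pain_nrs": rng.integers(0, 11, n).astype(float),
        "concomitant_analgesic": rng.integers(0, 2, n).astype(float),
        "grip_strength": rng.normal(20, 5, n),
        "bmi": rng.normal(28, 4, n),
        "age": rng.normal(62, 9, n),
        "gender": rng.choice(["F", "M"], n),
    })
    treat = (df["arm"] == "intervention").to_numpy(float)
    df["total_cost"] = (400 - 25 * treat + 0.6 * df["cost_baseline"]
                        + rng.gamma(2.0, 80.0, n))
    df["qaly"] = (0.25 + 0.012 * treat + 0.55 * df["u0"] + rng.normal(0, 0.06, n))
    return df
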