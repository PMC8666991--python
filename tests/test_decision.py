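"""ICER quadrant semantics, net benefit, CEAC and CE-plane invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trialcea.decision import (Threshold, ce_plane_export, ceac, icer,
                               net_benefit, net_health_benefit)
from trialcea.estimation import BootstrapCloud
from trialcea.schema import ValidationError

finite = st.floats(min_value=-1e4, max_value=1e4, allow_nan=False)


def test_southwest_cost_saved_per_qaly_lost():
    r = icer(-11.80, -0.0052)
    assert r.quadrant == "SW"
    assert r.interpretation == "cost saved per QALY lost"
    assert r.value == pytest.approx(2269.23, abs=0.01)
    assert r.value > 0


def test_northeast_ratio():
    r = icer(100.0, 0.01)
    assert r.quadrant == "NE" and r.value == pytest.approx(10_000.0)
    assert r.interpretation == "cost per QALY gained"


def test_dominance_states_have_no_ratio():
    se = icer(-1.0, 0.001)
    assert se.quadrant == "SE" and se.value is None and se.interpretation == "dominant"
    nw = icer(1.0, -0.001)
    assert nw.quadrant == "NW" and nw.value is None and nw.interpretation == "dominated"
    z = icer(5.0, 0.0)
    assert z.value is None and "zero effect" in z.interpretation


def test_net_benefit_values():
    assert net_benefit(-11.80, -0.0052, 20_000) == pytest.approx(-92.20)
    assert net_benefit(-11.80, -0.0052, 30_000) == pytest.approx(-144.20)
    assert net_benefit(0, 0, 12_345) == 0.0
    assert net_health_benefit(-11.80, -0.0052, 20_000) == pytest.approx(
        -0.0052 + 11.80 / 20_000)
    with pytest.raises(ValidationError):
        net_benefit(1.0, 1.0, 0)
    with pytest.raises(ValidationError):
        Threshold(-5)


@settings(max_examples=100, deadline=None)
@given(finite, finite, st.floats(min_value=1, max_value=1e5, allow_nan=False),
       st.floats(min_value=0.1, max_value=10, allow_nan=False))
def test_net_benefit_linear_in_lambda(dc, de, lam, k):
    nb1 = net_benefit(dc, de, lam)
    nbk = net_benefit(dc, de, k * lam)
    assert nbk - nb1 == pytest.approx((k - 1) * lam * de, rel=1e-9, abs=1e-6)


def test_ceac_dominant_cloud_probability_one():
    cloud = BootstrapCloud(delta_cost=-np.abs(np.random.default_rng(0).normal(50, 5, 200)),
                           delta_qaly=np.abs(np.random.default_rng(1).normal(0.01, 0.001, 200)))
    out = ceac(cloud, [500, 20_000, 30_000])
    assert (out["probability"] == 1.0).all()


def test_ceac_counting_and_brute_force_identity():
    cloud = BootstrapCloud(delta_cost=np.array([-1.0, 1.0]),
                           delta_qaly=np.array([0.0, 0.0]))
    out = ceac(cloud, [10_000])
    assert out["probability"].iloc[0] == 0.5  # net benefits {+1, -1}

    rng = np.random.default_rng(2)
    cloud2 = BootstrapCloud(delta_cost=rng.normal(0, 50, 300),
                            delta_qaly=rng.normal(0, 0.01, 300))
    grid = [1000.0, 20_000.0, 45_000.0]
    fast = ceac(cloud2, grid)["probability"].to_numpy()
    slow = [np.mean([lam * e - c > 0 for c, e in
                     zip(cloud2.delta_cost, cloud2.delta_qaly)]) for lam in grid]
    np.testing.assert_allclose(fast, slow)


def test_ceac_symmetric_cloud_near_half():
    rng = np.random.default_rng(3)
    dc = rng.normal(0, 30, 4000)
    de = rng.normal(0, 0.01, 4000)
    cloud = BootstrapCloud(delta_cost=np.concatenate([dc, -dc]),
                           delta_qaly=np.concatenate([de, -de]))
    out = ceac(cloud, np.linspace(500, 50_000, 12))
    assert np.allclose(out["probability"], 0.5, atol=3 * np.sqrt(0.25 / cloud.B))


def test_ceac_zero_net_benefit_counts_as_not_cost_effective():
    cloud = BootstrapCloud(delta_cost=np.array([0.0]), delta_qaly=np.array([0.0]))
    assert ceac(cloud, [20_000])["probability"].iloc[0] == 0.0


def test_ceac_empty_grid_rejected():
    cloud = BootstrapCloud(delta_cost=np.array([1.0]), delta_qaly=np.array([1.0]))
    with pytest.raises(ValidationError):
        ceac(cloud, [])


def test_ce_plane_origin_and_partition():
    origin = BootstrapCloud(delta_cost=np.zeros(5), delta_qaly=np.zeros(5))
    _, shares = ce_plane_export(origin)
    assert shares["NE"] == 1.0 and sum(shares.values()) == 1.0

    rng = np.random.default_rng(4)
    cloud = BootstrapCloud(delta_cost=rng.normal(0, 10, 501),
                           delta_qaly=rng.normal(0, 0.01, 501))
    df, shares = ce_plane_export(cloud)
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
    assert set(df.columns) >= {"replicate", "delta_cost", "delta_qaly", "quadrant"}


def test_ce_plane_symmetric_cloud_even_shares():
    rng = np.random.default_rng(5)
    dc = rng.normal(0, 10, 3000)
    de = rng.normal(0, 0.01, 3000)
    cloud = BootstrapCloud(delta_cost=np.concatenate([dc, -dc]),
                           delta_qaly=np.concatenate([de, -de]))
    _, shares = ce_plane_export(cloud)
    for q in ("NE", "SE", "SW", "NW"):
        assert shares[q] == pytest.approx(0.25, abs=0.02)


def test_cost_effectiveness_status_crosses_at_most_once():
    """For each replicate with nonzero effect, net benefit is monotone in
    lambda, so its sign changes at most once along an increasing grid."""
    rng = np.random.default_rng(6)
    cloud = BootstrapCloud(delta_cost=rng.normal(0, 30, 400),
                           delta_qaly=rng.normal(0, 0.01, 400))
    grid = np.linspace(100, 50_000, 200)
    nb = grid[:, None] * cloud.delta_qaly[None, :] - cloud.delta_cost[None, :]
    status = nb > 0
    nonzero = cloud.delta_qaly != 0
    flips = np.abs(np.diff(status[:, nonzero].astype(int), axis=0)).sum(axis=0)
    assert (flips <= 1).all()


def test_sw_symmetric_preference_rule_agrees_with_net_benefit():
    """In the south-west quadrant, |ICER| > lambda iff net benefit > 0."""
    rng = np.random.default_rng(7)
    dc = -np.abs(rng.normal(30, 10, 500))
    de = -np.abs(rng.normal(0.005, 0.002, 500)) - 1e-6
    for lam in (20_000.0, 30_000.0):
        ratio_rule = np.abs(dc / de) > lam
        nb_rule = net_benefit(dc, de, lam) > 0
        np.testing.assert_array_equal(ratio_rule, nb_rule)
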