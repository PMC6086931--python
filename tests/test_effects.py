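"""Health-effect modelling: utilization deltas, the calibrated
lives-saved proxy, and DALY discounting against independent oracles."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from mhealth_cea.effects import (
    ArmUtilization,
    DalyConfig,
    LivesSavedParameter,
    daly_per_death,
    effect_estimate,
    incremental_utilization,
    lives_saved_proxy,
    lives_to_dalys,
)
from mhealth_cea.synthetic import YEAR5_LIVES


INTERVENTION = ArmUtilization("intervention", 0.72, 0.95, 0.67, n=87)
COMPARISON = ArmUtilization("comparison", 0.46, 0.90, 0.39, n=90)


def test_year5_utilization_deltas():
    deltas = incremental_utilization(INTERVENTION, COMPARISON)
    assert deltas["anc4"] == pytest.approx(0.26)
    assert deltas["full_imm"] == pytest.approx(0.05)
    assert deltas["comprehensive"] == pytest.approx(0.28)


def test_identical_arms_give_zero_deltas():
    deltas = incremental_utilization(INTERVENTION, INTERVENTION)
    assert all(v == 0 for v in deltas.values())


def test_negative_deltas_are_valid():
    deltas = incremental_utilization(
        ArmUtilization("intervention", 0.40, 0.85, 0.30, n=87),
        ArmUtilization("comparison", 0.46, 0.90, 0.39, n=90),
    )
    assert deltas["anc4"] < 0


def test_utilization_invariants_enforced():
    with pytest.raises(ValueError):
        ArmUtilization("intervention", 0.5, 0.5, 0.6, n=87)  # cc > min
    with pytest.raises(ValueError):
        ArmUtilization("intervention", 1.2, 0.5, 0.4, n=87)


# --- lives-saved proxy ------------------------------------------------------

def test_self_calibration_reproduces_reference_scenario():
    point, low, high = lives_saved_proxy(0.28, 179_562, YEAR5_LIVES)
    assert point == pytest.approx(182.0)
    assert (low, high) == (pytest.approx(109.0), pytest.approx(199.0))


def test_year4_scenario_scales_linearly():
    point, _, _ = lives_saved_proxy(0.28, 57_214, YEAR5_LIVES)
    assert point == pytest.approx(58.0, abs=0.05)


def test_zero_users_zero_lives():
    assert lives_saved_proxy(0.28, 0, YEAR5_LIVES)[0] == 0


def test_zero_reference_delta_rejected():
    bad = LivesSavedParameter(182, 109, 199, 5, 179_562, 0.0)
    with pytest.raises(ValueError):
        lives_saved_proxy(0.28, 100, bad)


@settings(max_examples=100, derandomize=True)
@given(
    a=st.floats(min_value=0.01, max_value=10.0),
    delta=st.floats(min_value=0.01, max_value=0.5),
    users=st.floats(min_value=1, max_value=1e6),
)
def test_proxy_is_homogeneous_degree_one(a, delta, users):
    base, _, _ = lives_saved_proxy(delta, users, YEAR5_LIVES)
    scaled_users, _, _ = lives_saved_proxy(delta, a * users, YEAR5_LIVES)
    scaled_delta, _, _ = lives_saved_proxy(a * delta if a * delta <= 1 else delta,
                                           users, YEAR5_LIVES)
    assert scaled_users == pytest.approx(a * base, rel=1e-12)
    if a * delta <= 1:
        assert scaled_delta == pytest.approx(a * base, rel=1e-12)


# --- DALY discounting -------------------------------------------------------

def test_continuous_form_matches_numeric_integration():
    """Oracle: integrate exp(-rt) over [0, L] numerically."""
    r, L = 0.03, 66.0
    oracle, _ = quad(lambda t: math.exp(-r * t), 0, L)
    value = daly_per_death(DalyConfig(discount_rate=r, life_expectancy=L))
    assert value == pytest.approx(oracle, rel=1e-9)
    assert value == pytest.approx(28.73, abs=0.005)


def test_discrete_form_matches_explicit_sum():
    """Oracle: the explicit 66-term sum of annual discount factors."""
    r, L = 0.03, 66
    oracle = sum((1 + r) ** (-t) for t in range(1, L + 1))
    value = daly_per_death(
        DalyConfig(discount_rate=r, life_expectancy=L, discounting_form="discrete")
    )
    assert value == pytest.approx(oracle, rel=1e-9)
    assert value == pytest.approx(28.60, abs=0.01)


def test_undiscounted_limit_equals_life_expectancy():
    assert daly_per_death(DalyConfig(discount_rate=0.0)) == 66.0


def test_forms_agree_within_1_5_percent_and_converge_as_r_vanishes():
    c = daly_per_death(DalyConfig(discounting_form="continuous"))
    d = daly_per_death(DalyConfig(discounting_form="discrete"))
    assert abs(c - d) / d < 0.015
    for r in (1e-3, 1e-4, 1e-5):
        c = daly_per_death(DalyConfig(discount_rate=r))
        d = daly_per_death(DalyConfig(discount_rate=r, discounting_form="discrete"))
        assert abs(c - d) / d < r  # gap shrinks with r


@pytest.mark.parametrize("form", ["continuous", "discrete"])
def test_daly_factor_monotone_in_rate_and_life_expectancy(form):
    rates = [0.0, 0.01, 0.03, 0.05, 0.10]
    values = [
        daly_per_death(DalyConfig(discount_rate=r, discounting_form=form))
        for r in rates
    ]
    assert all(b < a for a, b in zip(values, values[1:]))  # decreasing in r
    lifes = [20, 40, 66, 80]
    values = [
        daly_per_death(DalyConfig(life_expectancy=L, discounting_form=form))
        for L in lifes
    ]
    assert all(b > a for a, b in zip(values, values[1:]))  # increasing in L


def test_lives_to_dalys():
    cfg = DalyConfig()
    assert lives_to_dalys(0, cfg) == 0
    assert lives_to_dalys(182, cfg) == pytest.approx(5228.9, abs=0.5)
    assert lives_to_dalys(100, DalyConfig(discount_rate=0.0)) == pytest.approx(6600)


def test_implied_published_daly_per_life_ratio_is_consistent():
    """The published year-5 ICERs (5652 per life, 200 per DALY) imply
    28.26 DALYs per life - within 2% of the discrete factor.  A
    consistency note, not an equality."""
    implied = 5652 / 200
    d = daly_per_death(DalyConfig(discounting_form="discrete"))
    assert abs(implied - d) / d < 0.02


def test_effect_estimate_bundles_lives_and_dalys():
    est = effect_estimate(0.28, 179_562, YEAR5_LIVES)
    assert est.lives_saved == pytest.approx(182.0)
    assert est.dalys_averted == pytest.approx(est.lives_saved * 28.731, rel=1e-3)
    assert est.dalys_low < est.dalys_averted < est.dalys_high


def test_daly_config_validation():
    with pytest.raises(ValueError):
        DalyConfig(discount_rate=1.0)
    with pytest.raises(ValueError):
        DalyConfig(life_expectancy=0)
    with pytest.raises(ValueError):
        DalyConfig(age_weighting=True)
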