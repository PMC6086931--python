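"""Monte Carlo machinery: parameter sampling, PSA reproducibility,
ICER summaries, acceptability curves, and tornado analysis."""

import numpy as np
import pandas as pd
import pytest

from mhealth_cea.uncertainty import (
    CEACurve,
    ParameterSpec,
    PSADraws,
    ceac,
    mean_icer,
    percentile_ci,
    run_psa,
    sample_parameters,
    tornado,
)


def make_draws(dc, de, seed=0):
    dc = np.asarray(dc, dtype=float)
    return PSADraws(dc, np.asarray(de, dtype=float), seed=seed, n_iter=len(dc))


# --- sampling ---------------------------------------------------------------

def test_fixed_family_is_constant():
    spec = ParameterSpec("x", 3.5, 3.5, 3.5, "fixed")
    table = sample_parameters([spec], 50, seed=1)
    assert (table["x"] == 3.5).all()


def test_beta_moment_matching():
    """beta(mean=0.5, effective_n=100): the analytic mean is the point;
    10,000 draws recover it within 0.01."""
    spec = ParameterSpec("p", 0.5, 0.0, 1.0, "beta", effective_n=100)
    draws = sample_parameters([spec], 10_000, seed=7)["p"]
    assert draws.mean() == pytest.approx(0.5, abs=0.01)
    assert draws.std() == pytest.approx(np.sqrt(0.25 / 101), rel=0.05)
    assert ((draws > 0) & (draws < 1)).all()


def test_uniform_range_mean_is_midpoint_not_point():
    """uniform(109, 199): the sample mean sits at the midpoint 154,
    regardless of where the point estimate lies in the range."""
    spec = ParameterSpec("lives", 182, 109, 199, "uniform")
    draws = sample_parameters([spec], 10_000, seed=3)["lives"]
    assert draws.mean() == pytest.approx(154, abs=1.5)


def test_pert_mean_is_mode_weighted():
    spec = ParameterSpec("lives", 182, 109, 199, "pert")
    draws = sample_parameters([spec], 20_000, seed=3)["lives"]
    assert draws.mean() == pytest.approx((109 + 4 * 182 + 199) / 6, abs=1.0)
    assert draws.min() >= 109 and draws.max() <= 199


def test_gamma_sd_from_range():
    spec = ParameterSpec("c", 0.08, 0.04, 0.11, "gamma")
    draws = sample_parameters([spec], 50_000, seed=11)["c"]
    assert draws.mean() == pytest.approx(0.08, rel=0.02)
    assert draws.std() == pytest.approx((0.11 - 0.04) / (2 * 1.96), rel=0.05)
    assert (draws >= 0).all()


def test_identical_seed_identical_table():
    specs = [
        ParameterSpec("p", 0.5, 0.0, 1.0, "beta", effective_n=50),
        ParameterSpec("c", 2.0, 1.0, 3.0, "gamma"),
    ]
    a = sample_parameters(specs, 500, seed=42)
    b = sample_parameters(specs, 500, seed=42)
    pd.testing.assert_frame_equal(a, b)
    c = sample_parameters(specs, 500, seed=43)
    assert not a.equals(c)


def test_adding_a_parameter_leaves_existing_columns_unchanged():
    """Per-parameter substreams: extending the spec list must not
    perturb the draws of existing parameters."""
    base = [ParameterSpec("p", 0.5, 0.0, 1.0, "beta", effective_n=50)]
    extended = base + [ParameterSpec("q", 0.2, 0.0, 1.0, "beta", effective_n=50)]
    a = sample_parameters(base, 200, seed=5)
    b = sample_parameters(extended, 200, seed=5)
    np.testing.assert_array_equal(a["p"].to_numpy(), b["p"].to_numpy())


def test_spec_validation():
    with pytest.raises(ValueError):
        ParameterSpec("x", 2.0, 1.0, 1.5, "uniform")  # point outside range
    with pytest.raises(ValueError):
        ParameterSpec("x", 0.5, 0.0, 1.5, "beta", effective_n=10)  # support
    with pytest.raises(ValueError):
        ParameterSpec("x", 0.5, 0.0, 1.0, "beta")  # missing effective_n
    with pytest.raises(ValueError):
        ParameterSpec("x", 0.5, 0.0, 1.0, "cauchy")


# --- PSA --------------------------------------------------------------------

def toy_model(v):
    return v["c"], v["e"]


TOY_SPECS = [
    ParameterSpec("c", 100.0, 90.0, 110.0, "gamma", sd=5.0),
    ParameterSpec("e", 10.0, 8.0, 12.0, "gamma", sd=1.0),
]


def test_all_fixed_specs_degenerate_to_point_estimate():
    specs = [
        ParameterSpec("c", 100.0, 100.0, 100.0, "fixed"),
        ParameterSpec("e", 10.0, 10.0, 10.0, "fixed"),
    ]
    draws = run_psa(specs, toy_model, n_iter=25, seed=1)
    assert (draws.delta_cost == 100.0).all()
    assert (draws.delta_effect == 10.0).all()
    assert mean_icer(draws) == pytest.approx(10.0)


def test_psa_seed_reproducibility_bitwise():
    a = run_psa(TOY_SPECS, toy_model, n_iter=300, seed=9)
    b = run_psa(TOY_SPECS, toy_model, n_iter=300, seed=9)
    np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
    np.testing.assert_array_equal(a.delta_effect, b.delta_effect)
    grid = np.arange(0, 50, 5.0)
    np.testing.assert_array_equal(ceac(a, grid).probability, ceac(b, grid).probability)
    assert percentile_ci(a) == percentile_ci(b)


def test_failing_iterations_flagged_and_capped():
    def flaky(v):
        if v["c"] > 100:
            raise RuntimeError("boom")
        return v["c"], v["e"]

    with pytest.raises(RuntimeError, match="failed"):
        run_psa(TOY_SPECS, flaky, n_iter=200, seed=2)

    def rare(v):
        return v["c"], v["e"]

    draws = run_psa(TOY_SPECS, rare, n_iter=200, seed=2)
    assert draws.failures == []


def test_quadrant_counts_sum_to_n_iter():
    rng = np.random.default_rng(0)
    draws = make_draws(rng.normal(0, 1, 400), rng.normal(0, 1, 400))
    assert sum(draws.quadrant_counts().values()) == 400


# --- summaries --------------------------------------------------------------

def test_mean_icer_is_ratio_of_means():
    assert mean_icer(make_draws([100, 300], [10, 10])) == pytest.approx(20.0)
    # distinguishes ratio-of-means (8.0) from mean-of-ratios (12.5)
    assert mean_icer(make_draws([100, 100], [5, 20])) == pytest.approx(8.0)
    assert mean_icer(make_draws([50], [5])) == pytest.approx(10.0)
    assert mean_icer(make_draws([1.0, -1.0], [1.0, -1.0])) is None


def test_percentile_ci_degenerate_and_order():
    lo, hi, excl = percentile_ci(make_draws([100] * 50, [10] * 50))
    assert lo == hi == pytest.approx(10.0)
    assert excl == 0


def test_percentile_ci_uniform_ratio_order_statistics():
    """1000 draws with ratio ~ U(0,1): the 95% interval approaches
    (0.025, 0.975)."""
    rng = np.random.default_rng(12)
    ratios = rng.uniform(0, 1, 1000)
    draws = make_draws(ratios, np.ones(1000))
    lo, hi, _ = percentile_ci(draws)
    assert lo == pytest.approx(0.025, abs=0.01)
    assert hi == pytest.approx(0.975, abs=0.01)
    assert lo <= np.median(ratios) <= hi


def test_percentile_ci_excludes_sign_mixed_draws():
    dc = [10.0, 20.0, 30.0, 40.0, -5.0] * 10
    de = [1.0, 1.0, 1.0, 1.0, -1.0] * 10
    lo, hi, excluded = percentile_ci(make_draws(dc, de))
    assert excluded == 10
    assert lo >= 0  # negative-effect draws did not contaminate the ratios


def test_percentile_ci_needs_enough_draws():
    with pytest.raises(ValueError):
        percentile_ci(make_draws([1.0] * 10, [1.0] * 10), level=0.95)
    with pytest.raises(ValueError):
        percentile_ci(make_draws([1.0], [0.0]))


# --- CEAC -------------------------------------------------------------------

def test_ceac_zero_wtp_all_costly():
    draws = make_draws([10, 20, 30], [1, 1, 1])
    curve = ceac(draws, [0.0])
    assert curve.probability[0] == 0.0


def test_ceac_hand_enumerated_example():
    """Four draws at lambda=20: NMB {10, -10, -30, 25} gives P = 0.5."""
    draws = make_draws([10, 30, 10, -5], [1, 1, -1, 1])
    assert ceac(draws, [20.0]).probability[0] == pytest.approx(0.5)


def test_ceac_monotone_when_effects_positive_and_limits():
    rng = np.random.default_rng(21)
    draws = make_draws(rng.normal(100, 30, 500), rng.uniform(0.5, 2.0, 500))
    grid = np.linspace(0, 500, 51)
    curve = ceac(draws, grid)
    assert (np.diff(curve.probability) >= 0).all()
    # as lambda -> infinity the probability approaches the share of
    # draws with positive incremental effect (here all of them)
    assert ceac(draws, [1e9]).probability[0] == 1.0


def test_ceac_ties_count_as_not_cost_effective():
    draws = make_draws([10.0], [1.0])
    assert ceac(draws, [10.0]).probability[0] == 0.0  # NMB exactly zero


def test_ceac_curve_validation():
    with pytest.raises(ValueError):
        CEACurve(np.array([1.0, 0.5]), np.array([0.1, 0.2]))
    with pytest.raises(ValueError):
        CEACurve(np.array([0.0, 1.0]), np.array([0.5, 1.4]))


# --- tornado ----------------------------------------------------------------

def test_tornado_toy_model_single_driver():
    specs = [
        ParameterSpec("c", 100.0, 90.0, 110.0, "uniform"),
        ParameterSpec("e", 1.0, 1.0, 1.0, "fixed"),
    ]
    entries = tornado(specs, toy_model)
    assert entries[0].parameter == "c"
    assert (entries[0].icer_at_low, entries[0].icer_at_high) == (90.0, 110.0)
    assert entries[1].width == 0.0  # degenerate bar retained


def test_tornado_sorted_descending_by_width():
    specs = [
        ParameterSpec("c", 100.0, 50.0, 150.0, "uniform"),
        ParameterSpec("e", 10.0, 9.0, 11.0, "uniform"),
    ]
    entries = tornado(specs, toy_model)
    widths = [e.width for e in entries]
    assert widths == sorted(widths, reverse=True)
    assert len(entries) == len(specs)
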