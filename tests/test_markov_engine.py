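"""Markov engine: matrices, traces, closed forms, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pa_cea import (ModelConfig, ParameterValidationError, SubcohortProfile,
                    build_matrix, expected_values, random_parameter_set,
                    run_cohort)
from pa_cea.markov_engine import _profile_totals


def profile(risk="cured", drug=0.0, upfront=0.0, mass=1.0):
    return SubcohortProfile("test", mass, upfront, drug, risk)


# -- transition matrices ----------------------------------------------------

def test_pa_row(params):
    m = build_matrix("pa", params)
    assert m[0] == pytest.approx([1 - 0.0042 - 0.0563 - 0.129,
                                  0.0563, 0.129, 0.0042])
    assert m[0, 0] == pytest.approx(0.8105)


def test_cured_row_stroke_entry(params):
    assert build_matrix("cured", params)[0, 2] == 0.0011


def test_structure_and_stochasticity(params):
    for risk in ("cured", "pa", "eht"):
        m = build_matrix(risk, params)
        assert m.sum(axis=1) == pytest.approx([1, 1, 1, 1], abs=1e-12)
        assert ((m >= 0) & (m <= 1)).all()
        assert m[3] == pytest.approx([0, 0, 0, 1])       # death absorbing
        assert m[1, 0] == m[1, 2] == 0                   # HF: only HF/death
        assert m[2, 0] == m[2, 1] == 0                   # stroke: only stroke/death


def test_zero_probability_matrix_is_identity_like(params):
    p0 = params.with_values({k: 0.0 for k in (
        "eht_death", "eht_hf", "eht_stroke", "hf_death", "stroke_death")})
    assert build_matrix("eht", p0) == pytest.approx(np.eye(4))


def test_competing_risks_above_one_rejected(params):
    with pytest.raises(ParameterValidationError, match="competing risks"):
        params.with_values({"pa_stroke": 0.8, "pa_hf": 0.3})


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_random_matrices_row_stochastic(seed):
    p = random_parameter_set(seed)
    for risk in ("cured", "pa", "eht"):
        m = build_matrix(risk, p)
        assert m.sum(axis=1) == pytest.approx([1, 1, 1, 1], abs=1e-12)


# -- cohort traces ----------------------------------------------------------

def test_single_cycle_end_reward_hand_computed(params, end_cycle_config):
    """One transition of the cured profile, no discounting: QALY is the
    post-transition occupancy-weighted utility."""
    p = params.with_value("discount_rate", 0.0)
    tr = run_cohort(profile("cured"), p, 1, end_cycle_config)
    expected = (1 - 0.00416 - 0.0266 - 0.0011) * 1.0 + (0.0266 + 0.0011) * 0.9
    assert tr.total_qaly == pytest.approx(expected)


def test_single_cycle_start_reward(params, config):
    """Start-of-cycle convention: the first cycle is spent in hypertension."""
    tr = run_cohort(profile("cured"), params, 1, config)
    assert tr.total_qaly == pytest.approx(1.0 / 1.02)


def test_no_event_limit(params, end_cycle_config):
    p = params.with_values({k: 0.0 for k in (
        "eht_death", "eht_hf", "eht_stroke")})
    tr = run_cohort(profile("eht"), p, 1, end_cycle_config)
    assert tr.total_qaly == pytest.approx(1.0 / 1.02)


def test_zero_cycles_disallowed(params, config):
    with pytest.raises(ValueError):
        run_cohort(profile(), params, 0, config)
    with pytest.raises(ValueError):
        expected_values("comprehensive", params, 0, config)


def test_occupancy_rows_are_probability_vectors(params, config):
    tr = run_cohort(profile("pa", drug=60_656), params, 38, config)
    assert tr.occupancy.sum(axis=1) == pytest.approx(
        np.ones(39), abs=1e-12)
    assert (tr.occupancy >= 0).all()


def test_cumulative_totals_non_decreasing(params, config):
    tr = run_cohort(profile("pa", drug=60_656, upfront=1000.0), params, 32,
                    config)
    assert (np.diff(tr.cumulative_cost) >= 0).all()
    assert (np.diff(tr.cumulative_qaly) >= 0).all()
    assert tr.cumulative_cost[0] == 1000.0


def test_eht_32_cycle_qaly_bracket(params, config):
    """Bounded above by the 2 %-discount annuity factor (~23.1)."""
    tr = run_cohort(profile("eht", drug=60_656), params, 32, config)
    assert 20 < tr.total_qaly < 24


def test_zero_discount_zero_mortality_closed_form(params, config):
    p = params.with_values({"discount_rate": 0.0, "eht_death": 0.0,
                            "eht_hf": 0.0, "eht_stroke": 0.0})
    for cycles in (1, 7, 40):
        tr = run_cohort(profile("eht"), p, cycles, config)
        assert tr.total_qaly == pytest.approx(cycles * p["u_eht"])


def test_trace_and_lean_totals_agree(params):
    """run_cohort and the scalar accumulator implement identical accounting."""
    for timing in ("start", "end", "half"):
        for t0 in (0, 1):
            cfg = ModelConfig(reward_timing=timing, discount_start_cycle=t0)
            pr = profile("pa", drug=61_144, upfront=5_000.0)
            tr = run_cohort(pr, params, 21, cfg)
            c, q = _profile_totals(pr, params, 21, cfg)
            assert tr.total_cost == pytest.approx(c, rel=1e-12)
            assert tr.total_qaly == pytest.approx(q, rel=1e-12)


def test_entry_costs_charged_once_per_entering_mass(params, config):
    """With only the HF-entry cost nonzero, total cost equals the
    discounted sum of newly entering HF mass times that cost."""
    zeroed = {p.id: 0.0 for p in params
              if p.category in ("cost_initial", "cost_annual")}
    zeroed["hf_initial"] = 1.0  # unit entry cost
    p = params.with_values(zeroed)
    tr = run_cohort(profile("eht"), p, 10, config)
    occ = tr.occupancy
    expected = sum(occ[t - 1, 0] * p["eht_hf"] * 1.02 ** (-t)
                   for t in range(1, 11))
    assert tr.total_cost == pytest.approx(expected)


# -- expected values and monotonicity --------------------------------------

def test_expected_values_mass_weighted(params, config):
    cost, qaly = expected_values("medication_only", params, 32, config)
    pa = _profile_totals(profile("pa", drug=60_656), params, 32, config)
    eht = _profile_totals(profile("eht", drug=60_656), params, 32, config)
    assert cost == pytest.approx(0.1 * pa[0] + 0.9 * eht[0])
    assert qaly == pytest.approx(0.1 * pa[1] + 0.9 * eht[1])


def test_raising_death_probability_lowers_qalys(params, config):
    base = expected_values("medication_only", params, 32, config)[1]
    for pid in ("pa_death", "eht_death", "hf_death", "stroke_death"):
        worse = params.with_value(pid, min(1.0, params[pid] * 3))
        assert expected_values("medication_only", worse, 32, config)[1] < base


def test_raising_discount_rate_lowers_both_totals(params, config):
    lo = expected_values("comprehensive", params, 32, config)
    hi = expected_values(
        "comprehensive", params.with_value("discount_rate", 0.05), 32, config)
    assert hi[0] < lo[0] and hi[1] < lo[1]


def test_short_horizon_cost_approaches_upfront(params, config):
    """At a 1-cycle horizon the cost is dominated by the expected upfront."""
    from pa_cea import resolve_strategy
    up = sum(p.mass * p.upfront_cost
             for p in resolve_strategy("comprehensive", params, config))
    cost, _ = expected_values("comprehensive", params, 1, config)
    annual = cost - up
    assert up == pytest.approx(121_520, rel=1e-3)
    assert 0 < annual < 250_000  # one discounted year of drugs and events
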