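"""Four-state annual-cycle Markov cohort engine.

States: hypertension (HTN), heart failure (HF), stroke, death.  The cohort
starts fully in HTN; each year it may transition to HF, stroke or death with
risk-profile-specific probabilities; HF and stroke are chronic states whose
only exit is death.  While in HTN the cohort pays its annual drug cost and
accrues the treated-hypertension utility; HF and stroke substitute their
follow-up costs and utilities; one-time event costs are charged to the mass
newly entering HF/stroke each cycle.  Costs and QALYs are discounted
annually and the upfront (diagnosis/treatment) cost is added undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, ModelConfig
from .decision_tree import Strategy, SubcohortProfile, resolve_strategy
from .parameters import RISK_PROFILE_ROWS, ParameterSet, ParameterValidationError

__all__ = [
    "STATES",
    "build_matrix",
    "run_cohort",
    "expected_values",
    "MarkovTrace",
]

STATES = ("htn", "hf", "stroke", "death")


def build_matrix(risk_profile: str, params: ParameterSet) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix for one risk profile."""
    try:
        d_id, h_id, s_id = RISK_PROFILE_ROWS[risk_profile]
    except KeyError:
        raise KeyError(f"unknown risk profile {risk_profile!r}") from None
    p_death, p_hf, p_stroke = params[d_id], params[h_id], params[s_id]
    stay = 1.0 - p_death - p_hf - p_stroke
    if stay < -1e-12:
        raise ParameterValidationError(
            f"{risk_profile}: competing risks sum to {1 - stay:.6f} > 1")
    hf_death = params["hf_death"]
    stroke_death = params["stroke_death"]
    m = np.array([
        [max(stay, 0.0), p_hf, p_stroke, p_death],
        [0.0, 1.0 - hf_death, 0.0, hf_death],
        [0.0, 0.0, 1.0 - stroke_death, stroke_death],
        [0.0, 0.0, 0.0, 1.0],
    ])
    if (m < -1e-12).any() or (m > 1 + 1e-12).any():
        raise ParameterValidationError(
            f"{risk_profile}: transition probabilities outside [0, 1]")
    assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
    return m


@dataclass
class MarkovTrace:
    """Per-cycle occupancy and reward record for one sub-cohort (unit mass).

    ``occupancy[t]`` is the state distribution after ``t`` transitions
    (row 0 is the initial all-HTN vector).  Cost/QALY arrays are per cycle
    ``t = 1..cycles``; cumulative arrays include the upfront cost at index 0.
    """

    occupancy: np.ndarray        # (cycles+1, 4)
    cost: np.ndarray             # (cycles,) undiscounted
    qaly: np.ndarray             # (cycles,) undiscounted
    cost_discounted: np.ndarray  # (cycles,)
    qaly_discounted: np.ndarray  # (cycles,)
    upfront_cost: float

    @property
    def cycles(self) -> int:
        return len(self.cost)

    @property
    def cumulative_cost(self) -> np.ndarray:
        return self.upfront_cost + np.concatenate(
            [[0.0], np.cumsum(self.cost_discounted)])

    @property
    def cumulative_qaly(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.qaly_discounted)])

    @property
    def total_cost(self) -> float:
        return self.upfront_cost + float(self.cost_discounted.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_discounted.sum())


def _reward_rates(profile: SubcohortProfile, params: ParameterSet,
                  config: ModelConfig) -> tuple[float, float, float]:
    """Annual state costs (HTN, HF, stroke) for a sub-cohort."""
    drug = profile.annual_drug_cost
    c_hf = params["hf_followup"]
    c_st = params["stroke_followup"]
    if config.drug_in_event_states:
        c_hf += drug
        c_st += drug
    return drug, c_hf, c_st


def run_cohort(
    profile: SubcohortProfile,
    params: ParameterSet,
    cycles: int,
    config: ModelConfig = DEFAULT_CONFIG,
) -> MarkovTrace:
    """Propagate one sub-cohort (per unit mass) and record the full trace."""
    if cycles < 1:
        raise ValueError(f"cycles must be >= 1, got {cycles}")
    m = build_matrix(profile.risk_profile, params)
    c_htn, c_hf, c_st = _reward_rates(profile, params, config)
    u_htn, u_hf, u_st = params["u_eht"], params["u_hf"], params["u_stroke"]
    hf_init, st_init = params["hf_initial"], params["stroke_initial"]
    r = params["discount_rate"]
    t0 = config.discount_start_cycle

    occ = np.zeros((cycles + 1, 4))
    occ[0, 0] = 1.0
    cost = np.zeros(cycles)
    qaly = np.zeros(cycles)
    disc = np.array([(1.0 + r) ** (-(t - 1 + t0)) for t in range(1, cycles + 1)])

    for t in range(1, cycles + 1):
        prev = occ[t - 1]
        new_hf = prev[0] * m[0, 1]
        new_st = prev[0] * m[0, 2]
        cur = prev @ m
        occ[t] = cur
        if config.reward_timing == "start":
            o = prev
        elif config.reward_timing == "end":
            o = cur
        else:
            o = 0.5 * (prev + cur)
        cost[t - 1] = (o[0] * c_htn + o[1] * c_hf + o[2] * c_st
                       + new_hf * hf_init + new_st * st_init)
        qaly[t - 1] = o[0] * u_htn + o[1] * u_hf + o[2] * u_st

    return MarkovTrace(
        occupancy=occ,
        cost=cost,
        qaly=qaly,
        cost_discounted=cost * disc,
        qaly_discounted=qaly * disc,
        upfront_cost=profile.upfront_cost,
    )


def _profile_totals(
    profile: SubcohortProfile,
    params: ParameterSet,
    cycles: int,
    config: ModelConfig,
) -> tuple[float, float]:
    """Discounted (cost, qaly) per unit mass -- lean scalar loop.

    Same accounting as :func:`run_cohort` without building the trace; the
    equivalence is asserted by the test suite.  Kept scalar because the
    sensitivity layers call it tens of thousands of times.
    """
    d_id, h_id, s_id = RISK_PROFILE_ROWS[profile.risk_profile]
    p_death, p_hf, p_stroke = params[d_id], params[h_id], params[s_id]
    stay = 1.0 - p_death - p_hf - p_stroke
    if stay < -1e-12:
        raise ParameterValidationError(
            f"{profile.risk_profile}: competing risks sum above 1")
    hf_stay = 1.0 - params["hf_death"]
    st_stay = 1.0 - params["stroke_death"]
    c_htn, c_hf, c_st = _reward_rates(profile, params, config)
    u_htn, u_hf, u_st = params["u_eht"], params["u_hf"], params["u_stroke"]
    hf_init, st_init = params["hf_initial"], params["stroke_initial"]
    v = 1.0 / (1.0 + params["discount_rate"])
    disc = 1.0 if config.discount_start_cycle == 0 else v
    timing = config.reward_timing

    htn, hf, st = 1.0, 0.0, 0.0
    cost = profile.upfront_cost
    qaly = 0.0
    for _ in range(cycles):
        new_hf = htn * p_hf
        new_st = htn * p_stroke
        n_htn = htn * stay
        n_hf = hf * hf_stay + new_hf
        n_st = st * st_stay + new_st
        if timing == "start":
            o0, o1, o2 = htn, hf, st
        elif timing == "end":
            o0, o1, o2 = n_htn, n_hf, n_st
        else:
            o0, o1, o2 = (htn + n_htn) * 0.5, (hf + n_hf) * 0.5, (st + n_st) * 0.5
        cost += (o0 * c_htn + o1 * c_hf + o2 * c_st
                 + new_hf * hf_init + new_st * st_init) * disc
        qaly += (o0 * u_htn + o1 * u_hf + o2 * u_st) * disc
        disc *= v
        htn, hf, st = n_htn, n_hf, n_st
    return cost, qaly


def expected_values(
    strategy: Strategy | str,
    params: ParameterSet,
    cycles: int,
    config: ModelConfig = DEFAULT_CONFIG,
) -> tuple[float, float]:
    """Mass-weighted expected (discounted cost, discounted QALY) of a strategy."""
    if cycles < 1:
        raise ValueError(f"cycles must be >= 1, got {cycles}")
    total_cost = 0.0
    total_qaly = 0.0
    for profile in resolve_strategy(strategy, params, config):
        c, q = _profile_totals(profile, params, cycles, config)
        total_cost += profile.mass * c
        total_qaly += profile.mass * q
    return total_cost, total_qaly
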