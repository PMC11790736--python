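"""Validation instruments: individual-level microsimulation and random inputs.

:func:`microsimulate` routes simulated individuals through the decision tree
by categorical sampling and steps each through the Markov chain year by
year, applying the same cost/utility/discount accounting rules as the cohort
engine but through an independent implementation (vectorised per-individual
state stepping, not occupancy-vector propagation).  Its means are unbiased
estimators of the cohort engine's expected values, which makes it an oracle
for the analytic pipeline.

:func:`random_parameter_set` draws random but valid parameter sets for
property-based testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, ModelConfig
from .decision_tree import Strategy, resolve_strategy
from .parameters import (RISK_PROFILE_ROWS, ParameterSet, default_parameters)

__all__ = ["MicrosimResult", "microsimulate", "random_parameter_set"]

# state codes for the individual-level simulation
_HTN, _HF, _STROKE, _DEATH = 0, 1, 2, 3


@dataclass
class MicrosimResult:
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    n_individuals: int
    states: np.ndarray | None = None  # (n, cycles+1) int8 paths if requested


def microsimulate(
    strategy: Strategy | str,
    params: ParameterSet,
    n_individuals: int = 100_000,
    cycles: int | None = None,
    seed: int | None = 0,
    config: ModelConfig = DEFAULT_CONFIG,
    sex: str = "male",
    keep_paths: bool = False,
) -> MicrosimResult:
    """Monte-Carlo estimate of a strategy's expected cost and QALYs."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if cycles is None:
        cycles = params.cycles(sex)
    rng = np.random.default_rng(seed)

    profiles = resolve_strategy(strategy, params, config)
    masses = np.array([p.mass for p in profiles])
    assignment = rng.choice(len(profiles), size=n_individuals, p=masses)

    cost = np.empty(n_individuals)
    qaly = np.zeros(n_individuals)
    all_states = (np.empty((n_individuals, cycles + 1), dtype=np.int8)
                  if keep_paths else None)

    v = 1.0 / (1.0 + params["discount_rate"])
    disc0 = 1.0 if config.discount_start_cycle == 0 else v
    u = np.array([params["u_eht"], params["u_hf"], params["u_stroke"], 0.0])
    hf_init, st_init = params["hf_initial"], params["stroke_initial"]

    for k, prof in enumerate(profiles):
        idx = np.flatnonzero(assignment == k)
        if idx.size == 0:
            continue
        n = idx.size
        d_id, h_id, s_id = RISK_PROFILE_ROWS[prof.risk_profile]
        p_death, p_hf, p_stroke = params[d_id], params[h_id], params[s_id]
        # cumulative thresholds for HTN exits: HF | stroke | death | stay
        t_hf = p_hf
        t_st = p_hf + p_stroke
        t_de = p_hf + p_stroke + p_death
        hf_die = params["hf_death"]
        st_die = params["stroke_death"]
        c_state = np.array([prof.annual_drug_cost,
                            params["hf_followup"], params["stroke_followup"],
                            0.0])
        if config.drug_in_event_states:
            c_state[1] += prof.annual_drug_cost
            c_state[2] += prof.annual_drug_cost

        state = np.zeros(n, dtype=np.int8)
        c = np.full(n, float(prof.upfront_cost))
        q = np.zeros(n)
        if keep_paths:
            all_states[idx, 0] = _HTN
        disc = disc0
        for t in range(1, cycles + 1):
            draw = rng.random(n)
            nxt = state.copy()
            in_htn = state == _HTN
            nxt[in_htn & (draw < t_hf)] = _HF
            nxt[in_htn & (draw >= t_hf) & (draw < t_st)] = _STROKE
            nxt[in_htn & (draw >= t_st) & (draw < t_de)] = _DEATH
            in_hf = state == _HF
            nxt[in_hf & (draw < hf_die)] = _DEATH
            in_st = state == _STROKE
            nxt[in_st & (draw < st_die)] = _DEATH

            new_hf = in_htn & (nxt == _HF)
            new_st = in_htn & (nxt == _STROKE)
            if config.reward_timing == "start":
                c_cycle = c_state[state]
                u_cycle = u[state]
            elif config.reward_timing == "end":
                c_cycle = c_state[nxt]
                u_cycle = u[nxt]
            else:
                c_cycle = 0.5 * (c_state[state] + c_state[nxt])
                u_cycle = 0.5 * (u[state] + u[nxt])
            c += (c_cycle + new_hf * hf_init + new_st * st_init) * disc
            q += u_cycle * disc
            disc *= v
            state = nxt
            if keep_paths:
                all_states[idx, t] = state
        cost[idx] = c
        qaly[idx] = q

    if n_individuals > 1:
        se_cost = float(cost.std(ddof=1) / np.sqrt(n_individuals))
        se_qaly = float(qaly.std(ddof=1) / np.sqrt(n_individuals))
    else:
        se_cost = se_qaly = float("nan")
    return MicrosimResult(
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=se_cost,
        se_qaly=se_qaly,
        n_individuals=n_individuals,
        states=all_states,
    )


def random_parameter_set(
    seed: int | np.random.Generator | None = None,
    max_exit_probability: float = 0.9,
) -> ParameterSet:
    """A random but valid parameter set for property tests.

    Costs are drawn log-uniformly around realistic magnitudes, probabilities
    uniformly with competing-risk rows kept feasible, utilities in [0.5, 1],
    discount in [0, 0.05] and cycle counts in 1..60.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    base = default_parameters()
    values: dict[str, float] = {}
    for p in base:
        if p.category in ("cost_initial", "cost_annual"):
            values[p.id] = float(p.value * np.exp(rng.uniform(-1.0, 1.0)))
        elif p.category == "utility":
            values[p.id] = float(rng.uniform(0.5, 1.0))
        elif p.category == "tree_probability":
            values[p.id] = float(rng.uniform(0.0, 1.0))
        elif p.category == "discount":
            values[p.id] = float(rng.uniform(0.0, 0.05))
        elif p.category == "cycles":
            values[p.id] = float(rng.integers(1, 61))
    for _profile, row in RISK_PROFILE_ROWS.items():
        raw = rng.uniform(0.0, 1.0, size=3)
        total = raw.sum()
        if total > max_exit_probability:
            raw *= rng.uniform(0.1, max_exit_probability) / total
        for pid, val in zip(row, raw):
            values[pid] = float(val)
    for pid in ("hf_death", "stroke_death"):
        values[pid] = float(rng.uniform(0.0, max_exit_probability))
    return base.with_values(values)
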