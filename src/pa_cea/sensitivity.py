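"""Sensitivity layers: one-way DSA (tornado), horizon sweep, Monte-Carlo PSA.

* :func:`tornado` varies one parameter at a time across its DSA range,
  re-running the full pipeline at each endpoint, and ranks parameters by the
  ICER spread they induce.
* :func:`cycle_sweep` varies the model horizon (a proxy for remaining life
  expectancy) and finds the fractional year at which the ICER falls below
  the willingness-to-pay threshold.
* :func:`psa` jointly samples all non-fixed parameters -- method-of-moments
  beta for probabilities (sd = 10 % of mean) and utilities (sd = 5 %), gamma
  for costs (sd = 10 %) -- and evaluates the incremental cost and QALYs of
  each draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cea import WTP_THRESHOLD
from .config import DEFAULT_CONFIG, ModelConfig
from .markov_engine import expected_values
from .parameters import PSA_CV, ParameterSet

__all__ = [
    "DsaRecord", "tornado", "SweepResult", "cycle_sweep",
    "PsaResult", "psa", "dsa_parameter_ids",
]


def dsa_parameter_ids(params: ParameterSet) -> list[str]:
    """Parameters varied in the DSA: everything except the cycle counts."""
    return [p.id for p in params if p.category != "cycles"]


#: the 26 parameters of the published tornado: one-time diagnosis/treatment
#: costs, decision-tree probabilities, Markov transition probabilities and
#: the discount rate (annual medication costs and utilities excluded)
TORNADO_PARAM_IDS: tuple[str, ...] = (
    "screening_tests", "ct_avs", "hf_initial", "stroke_initial",
    "surgery", "rfa",
    "prev_pa", "avs_success", "prev_apa_savs", "p_rfa_given_apa",
    "surg_success_savs", "rfa_success", "drugfree_surgery", "drugfree_rfa",
    "cured_death", "cured_hf", "cured_stroke",
    "pa_death", "pa_hf", "pa_stroke",
    "eht_death", "eht_hf", "eht_stroke",
    "hf_death", "stroke_death",
    "discount_rate",
)


@dataclass(frozen=True)
class DsaRecord:
    param_id: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _pipeline_icer(params: ParameterSet, sex: str, intervention: str,
                   reference: str, config: ModelConfig) -> float:
    cycles = params.cycles(sex)
    ci, qi = expected_values(intervention, params, cycles, config)
    cr, qr = expected_values(reference, params, cycles, config)
    de = qi - qr
    if de == 0.0:
        return float("nan")
    return (ci - cr) / de


def tornado(
    params: ParameterSet,
    sex: str = "male",
    intervention: str = "comprehensive",
    reference: str = "medication_only",
    config: ModelConfig = DEFAULT_CONFIG,
    param_ids: list[str] | None = None,
) -> list[DsaRecord]:
    """One-way DSA over each parameter's range, sorted by spread descending."""
    if param_ids is None:
        param_ids = dsa_parameter_ids(params)
    records = []
    for pid in param_ids:
        low, high = params.dsa_range(pid)
        icer_lo = _pipeline_icer(params.with_value(pid, low), sex,
                                 intervention, reference, config)
        icer_hi = _pipeline_icer(params.with_value(pid, high), sex,
                                 intervention, reference, config)
        records.append(DsaRecord(pid, low, high, icer_lo, icer_hi))
    return sorted(records, key=lambda rec: rec.spread, reverse=True)


@dataclass
class SweepResult:
    horizons: np.ndarray          # integer cycle counts evaluated
    icers: np.ndarray             # ICER at each horizon
    threshold_years: float | None  # interpolated crossing, None if no crossing
    monotone: bool
    crossings: list[float] = field(default_factory=list)


def cycle_sweep(
    params: ParameterSet,
    intervention: str = "comprehensive",
    reference: str = "medication_only",
    config: ModelConfig = DEFAULT_CONFIG,
    wtp: float = WTP_THRESHOLD,
    max_years: int = 50,
) -> SweepResult:
    """Horizon at which the ICER falls below the WTP threshold.

    Evaluates integer horizons 1..max_years and locates the crossing by
    linear interpolation between adjacent integers (0.01-year resolution).
    """
    horizons = np.arange(1, max_years + 1)
    icers = np.empty(len(horizons))
    for i, t in enumerate(horizons):
        ci, qi = expected_values(intervention, params, int(t), config)
        cr, qr = expected_values(reference, params, int(t), config)
        de = qi - qr
        icers[i] = (ci - cr) / de if de > 0 else np.inf

    finite = np.isfinite(icers)
    monotone = bool(np.all(np.diff(icers[finite]) <= 1e-9))
    crossings: list[float] = []
    for i in range(1, len(horizons)):
        a, b = icers[i - 1], icers[i]
        if np.isfinite(a) and np.isfinite(b) and a > wtp >= b:
            frac = (a - wtp) / (a - b)
            crossings.append(round(float(horizons[i - 1] + frac), 2))
        elif not np.isfinite(a) and np.isfinite(b) and b <= wtp:
            crossings.append(float(horizons[i]))
    threshold = crossings[0] if crossings else None
    return SweepResult(horizons, icers, threshold, monotone, crossings)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _beta_moments(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    if var <= 0 or var >= mean * (1.0 - mean):
        raise ValueError(f"infeasible beta moments: mean={mean}, sd={sd}")
    k = mean * (1.0 - mean) / var - 1.0
    return mean * k, (1.0 - mean) * k


@dataclass
class PsaResult:
    incr_cost: np.ndarray
    incr_qaly: np.ndarray
    below_wtp: np.ndarray
    n_redraws: int
    wtp: float
    sampled: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.incr_cost)

    @property
    def fraction_below_wtp(self) -> float:
        return float(self.below_wtp.mean())


def sample_parameter_sets(
    params: ParameterSet,
    n_draws: int,
    rng: np.random.Generator,
    max_redraw_rounds: int = 100,
) -> tuple[dict[str, np.ndarray], int]:
    """Draw ``n_draws`` joint parameter vectors; returns (samples, n_redraws).

    Parameters are sampled independently.  Competing-risk rows whose exit
    probabilities exceed 1 are rejected and redrawn as a whole row; the
    number of redrawn rows is reported.
    """
    samples: dict[str, np.ndarray] = {}
    for p in params:
        if p.psa_family == "fixed":
            samples[p.id] = np.full(n_draws, p.value)
        elif p.psa_family == "gamma":
            cv = PSA_CV[p.category]
            sd = cv * p.value
            shape = (p.value / sd) ** 2
            scale = sd * sd / p.value
            samples[p.id] = rng.gamma(shape, scale, size=n_draws)
        else:  # beta
            cv = PSA_CV[p.category]
            try:
                a, b = _beta_moments(p.value, cv * p.value)
            except ValueError:
                samples[p.id] = np.full(n_draws, p.value)
                continue
            samples[p.id] = rng.beta(a, b, size=n_draws)

    from .parameters import RISK_PROFILE_ROWS

    n_redraws = 0
    for _profile, (d, h, s) in RISK_PROFILE_ROWS.items():
        for _ in range(max_redraw_rounds):
            bad = samples[d] + samples[h] + samples[s] > 1.0
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            n_redraws += n_bad
            for pid in (d, h, s):
                p = params.get(pid)
                if p.psa_family != "beta":
                    continue
                cv = PSA_CV[p.category]
                a, b = _beta_moments(p.value, cv * p.value)
                samples[pid][bad] = rng.beta(a, b, size=n_bad)
        else:
            raise RuntimeError("competing-risk rejection did not converge")
    return samples, n_redraws


def psa(
    params: ParameterSet,
    sex: str = "male",
    n_draws: int = 10_000,
    seed: int | None = 0,
    intervention: str = "comprehensive",
    reference: str = "medication_only",
    config: ModelConfig = DEFAULT_CONFIG,
    wtp: float = WTP_THRESHOLD,
    keep_samples: bool = False,
) -> PsaResult:
    """Monte-Carlo PSA: evaluate the full pipeline for each joint draw."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    samples, n_redraws = sample_parameter_sets(params, n_draws, rng)
    cycles = params.cycles(sex)

    varied = [pid for pid in samples
              if params.get(pid).psa_family != "fixed"]
    dc = np.empty(n_draws)
    de = np.empty(n_draws)
    for i in range(n_draws):
        drawn = params.with_values({pid: float(samples[pid][i])
                                    for pid in varied})
        ci, qi = expected_values(intervention, drawn, cycles, config)
        cr, qr = expected_values(reference, drawn, cycles, config)
        dc[i] = ci - cr
        de[i] = qi - qr

    below = dc <= wtp * de
    return PsaResult(dc, de, below, n_redraws, wtp,
                     sampled=samples if keep_samples else {})
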