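"""Incremental cost-effectiveness: ICERs, dominance, WTP preference.

ICER = incremental cost / incremental QALYs, on the JPY-per-QALY scale.
A strategy *dominates* the reference when it is cheaper and more effective;
it is *dominated* when costlier and less effective.  Preference uses a
societal willingness-to-pay threshold of 5,000,000 JPY per QALY (inclusive
at the boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .config import DEFAULT_CONFIG, ModelConfig
from .decision_tree import STRATEGIES
from .markov_engine import expected_values
from .parameters import ParameterSet

__all__ = ["WTP_THRESHOLD", "CeaResult", "icer", "compare_all"]

WTP_THRESHOLD = 5_000_000.0  # JPY per QALY


@dataclass(frozen=True)
class CeaResult:
    strategy: str
    expected_cost: float
    expected_qaly: float
    incr_cost: float | None = None
    incr_qaly: float | None = None
    icer: float | None = None
    classification: str = "reference"  # icer | dominant | dominated | NA
    preferred: bool | None = None


def icer(
    intervention: tuple[float, float],
    reference: tuple[float, float],
    strategy: str = "intervention",
    wtp: float = WTP_THRESHOLD,
) -> CeaResult:
    """Compare (cost, qaly) pairs evaluated on identical inputs."""
    cost_i, qaly_i = intervention
    cost_r, qaly_r = reference
    dc = cost_i - cost_r
    de = qaly_i - qaly_r
    if dc < 0 and de > 0:
        return CeaResult(strategy, cost_i, qaly_i, dc, de, None, "dominant", True)
    if dc > 0 and de < 0:
        return CeaResult(strategy, cost_i, qaly_i, dc, de, None, "dominated", False)
    if de == 0.0:
        # equal effectiveness: no ratio; cheaper-or-equal is preferred
        return CeaResult(strategy, cost_i, qaly_i, dc, de, None, "NA", dc <= 0)
    ratio = dc / de
    if de > 0:
        preferred = ratio <= wtp
    else:  # cheaper and less effective: acceptable if savings per QALY
        preferred = ratio >= wtp  # forgone exceed the threshold
    return CeaResult(strategy, cost_i, qaly_i, dc, de, ratio, "icer", preferred)


def compare_all(
    params: ParameterSet,
    sex: str = "male",
    config: ModelConfig = DEFAULT_CONFIG,
    reference: str = "medication_only",
    wtp: float = WTP_THRESHOLD,
) -> pd.DataFrame:
    """Evaluate all five strategies against the reference for one sex."""
    cycles = params.cycles(sex)
    values = {sid: expected_values(sid, params, cycles, config)
              for sid in STRATEGIES}
    ref = values[reference]
    rows = []
    for sid, val in values.items():
        if sid == reference:
            res = CeaResult(sid, val[0], val[1])
        else:
            res = icer(val, ref, strategy=sid, wtp=wtp)
        rows.append({
            "strategy": sid,
            "sex": sex,
            "cost": res.expected_cost,
            "qaly": res.expected_qaly,
            "incr_cost": res.incr_cost if res.incr_cost is not None else math.nan,
            "incr_qaly": res.incr_qaly if res.incr_qaly is not None else math.nan,
            "icer": res.icer if res.icer is not None else math.nan,
            "classification": res.classification,
            "preferred": res.preferred,
        })
    return pd.DataFrame(rows).set_index("strategy")
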