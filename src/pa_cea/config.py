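"""Structural conventions of the model.

The source material leaves several structural choices open (where treated but
uncured patients sit in the Markov model, when cycle rewards accrue, how the
first cycle is discounted, whether medication costs continue after a heart-
failure or stroke event).  They are exposed here as explicit switches; the
defaults are the combination that best reproduces the published results
table and are frozen (see docs/methods.md for the calibration evidence).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ModelConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class ModelConfig:
    #: Markov risk profile for medically managed PA: bilateral hyperplasia,
    #: AVS failures and failed ablations.  "pa" keeps their elevated
    #: complication risk; "eht" treats them like controlled essential
    #: hypertension.
    treated_pa_risk: str = "pa"

    #: Risk profile after surgical excision of an adenoma when clinical
    #: success is absent.  "cured": the aldosterone source is removed, so
    #: all excised patients follow cured-PA transitions and the clinical-
    #: success / drug-free tiers drive medication costs only.  "treated":
    #: lack of clinical success leaves the patient at `treated_pa_risk`.
    excision_failure_risk: str = "cured"

    #: Segmental localization is required to target ablation; under
    #: conventional (central-vein) AVS the lesion cannot be targeted and
    #: ablation yields no clinical success.
    rfa_requires_segmental: bool = True

    #: When cycle rewards accrue: state membership at the start of the cycle
    #: ("start"), after the transition ("end"), or the average ("half") --
    #: the usual half-cycle correction.
    reward_timing: str = "start"

    #: Discount exponent of the first cycle: 1 discounts every cycle,
    #: 0 leaves the first cycle undiscounted.
    discount_start_cycle: int = 1

    #: Charge the annual drug cost in the heart-failure/stroke states on top
    #: of their follow-up costs.  Off by default: the follow-up costs are the
    #: annual costs of those states.
    drug_in_event_states: bool = False

    def __post_init__(self) -> None:
        if self.treated_pa_risk not in ("pa", "eht"):
            raise ValueError("treated_pa_risk must be 'pa' or 'eht'")
        if self.excision_failure_risk not in ("cured", "treated"):
            raise ValueError("excision_failure_risk must be 'cured' or 'treated'")
        if self.reward_timing not in ("start", "end", "half"):
            raise ValueError("reward_timing must be 'start', 'end' or 'half'")
        if self.discount_start_cycle not in (0, 1):
            raise ValueError("discount_start_cycle must be 0 or 1")


DEFAULT_CONFIG = ModelConfig()
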