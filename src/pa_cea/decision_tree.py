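"""Diagnosis-and-treatment phase: resolve a strategy into sub-cohorts.

Each treatment strategy partitions the hypertensive cohort into weighted
sub-cohorts.  A sub-cohort carries the one-time (upfront) cost accumulated
along its branch of the decision tree, the annual drug cost it pays while in
the hypertension state, and the Markov risk profile it follows afterwards
(``cured`` / ``pa`` / ``eht``).

Workup strategies screen the whole cohort (ARR + loading tests); confirmed
PA patients (prevalence ``prev_pa``) undergo CT + AVS; among successful AVS,
a fraction ``prev_apa_*`` have surgical PA (APA) and are excised by surgery
or -- in RFA strategies -- ablated with probability ``p_rfa_given_apa``;
the remainder (bilateral hyperplasia) stay on medication.  The medication-
only reference treats everyone as essential hypertension without workup;
its undiagnosed PA fraction keeps the elevated untreated-PA risk.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import DEFAULT_CONFIG, ModelConfig
from .parameters import ParameterSet

__all__ = ["Strategy", "STRATEGIES", "SubcohortProfile", "resolve_strategy"]

MASS_TOL = 1e-12


@dataclass(frozen=True)
class Strategy:
    id: str
    uses_savs: bool
    uses_rfa: bool
    is_workup: bool
    label: str = ""


STRATEGIES: dict[str, Strategy] = {
    s.id: s
    for s in (
        Strategy("comprehensive", True, True, True,
                 "comprehensive (sAVS with RFA)"),
        Strategy("savs_no_rfa", True, False, True, "sAVS without RFA"),
        Strategy("cavs_rfa", False, True, True, "cAVS with RFA"),
        Strategy("cavs_no_rfa", False, False, True, "cAVS without RFA"),
        Strategy("medication_only", False, False, False, "medication only"),
    )
}


@dataclass(frozen=True)
class SubcohortProfile:
    label: str
    mass: float
    upfront_cost: float
    annual_drug_cost: float
    risk_profile: str

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"{self.label}: negative mass {self.mass}")
        if self.upfront_cost < 0:
            raise ValueError(f"{self.label}: negative upfront cost")
        if self.risk_profile not in ("cured", "pa", "eht"):
            raise ValueError(f"{self.label}: unknown risk {self.risk_profile!r}")


def _as_strategy(strategy: Strategy | str) -> Strategy:
    if isinstance(strategy, Strategy):
        return strategy
    try:
        return STRATEGIES[strategy]
    except KeyError:
        raise KeyError(
            f"unknown strategy {strategy!r}; one of {sorted(STRATEGIES)}"
        ) from None


def resolve_strategy(
    strategy: Strategy | str,
    params: ParameterSet,
    config: ModelConfig = DEFAULT_CONFIG,
    keep_zero_mass: bool = False,
) -> list[SubcohortProfile]:
    """Partition the cohort for one strategy.

    Masses always sum to 1; upfront costs compose additively along each
    branch; zero-mass branches are dropped unless ``keep_zero_mass``.
    """
    strategy = _as_strategy(strategy)
    p = params
    prev_pa = p["prev_pa"]
    out: list[SubcohortProfile] = []

    if not strategy.is_workup:
        # PA goes undiagnosed: treated as essential hypertension, but keeps
        # the untreated-PA complication risk
        out.append(SubcohortProfile(
            "undiagnosed PA on standard drugs", prev_pa, 0.0, p["drug_eht"], "pa"))
        out.append(SubcohortProfile(
            "essential hypertension", 1.0 - prev_pa, 0.0, p["drug_eht"], "eht"))
        return _finish(out, keep_zero_mass)

    screening = p["screening_tests"]
    workup = screening + p["ct_avs"]
    treated = config.treated_pa_risk

    out.append(SubcohortProfile(
        "essential hypertension (screened)", 1.0 - prev_pa, screening,
        p["drug_eht"], "eht"))

    # AVS failure: diagnosed PA, not localizable, medicated
    avs_fail = prev_pa * (1.0 - p["avs_success"])
    out.append(SubcohortProfile(
        "AVS failure, medicated PA", avs_fail, workup,
        p["drug_pa_unoperated"], treated))

    prev_apa = p["prev_apa_savs"] if strategy.uses_savs else p["prev_apa_cavs"]
    surg_success = (p["surg_success_savs"] if strategy.uses_savs
                    else p["surg_success_cavs"])
    avs_ok = prev_pa * p["avs_success"]

    # bilateral hyperplasia: no surgical target, medicated
    out.append(SubcohortProfile(
        "bilateral hyperplasia, medicated PA", avs_ok * (1.0 - prev_apa),
        workup, p["drug_pa_unoperated"], treated))

    apa = avs_ok * prev_apa
    # (mass, label, upfront, success prob, drug-free prob, excised?)
    arms = []
    if strategy.uses_rfa:
        rfa_success = p["rfa_success"]
        if config.rfa_requires_segmental and not strategy.uses_savs:
            rfa_success = 0.0  # ablation cannot be targeted without sAVS
        arms.append((apa * p["p_rfa_given_apa"], "RFA",
                     workup + p["rfa"], rfa_success, p["drugfree_rfa"], False))
        arms.append((apa * (1.0 - p["p_rfa_given_apa"]), "surgery",
                     workup + p["surgery"], surg_success,
                     p["drugfree_surgery"], True))
    else:
        arms.append((apa, "surgery", workup + p["surgery"], surg_success,
                     p["drugfree_surgery"], True))

    for mass, label, upfront, success, drugfree, excised in arms:
        out.append(SubcohortProfile(
            f"APA {label}, success, drug-free", mass * success * drugfree,
            upfront, 0.0, "cured"))
        out.append(SubcohortProfile(
            f"APA {label}, success, on drugs", mass * success * (1.0 - drugfree),
            upfront, p["drug_success"], "cured"))
        # no clinical success: an excised gland still removes the aldosterone
        # source; a failed ablation leaves it intact
        if excised and config.excision_failure_risk == "cured":
            fail_risk = "cured"
        else:
            fail_risk = treated
        out.append(SubcohortProfile(
            f"APA {label}, no clinical success", mass * (1.0 - success),
            upfront, p["drug_partial_success"], fail_risk))

    return _finish(out, keep_zero_mass)


def _finish(profiles: list[SubcohortProfile],
            keep_zero_mass: bool) -> list[SubcohortProfile]:
    total = sum(pr.mass for pr in profiles)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"sub-cohort masses sum to {total!r}, expected 1")
    if not keep_zero_mass:
        profiles = [pr for pr in profiles if pr.mass > 0.0]
    return profiles
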