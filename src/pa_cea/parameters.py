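"""Model inputs: costs, utilities, probabilities and horizons.

Every quantity the model consumes is a :class:`Parameter` with a point
estimate, units, a deterministic-sensitivity (DSA) range and a probabilistic-
sensitivity (PSA) distribution family.  The shipped defaults are the published
Japanese healthcare-payer inputs for the primary-aldosteronism treatment
model: one-time diagnosis/treatment costs and annual medication/follow-up
costs in JPY, state utilities, decision-tree branch probabilities, annual
Markov transition probabilities, a 2 %/year discount rate and sex-specific
horizons (32/38 one-year cycles for 50-year-old men/women).

DSA ranges follow category-wide deviations: +/-20 % for costs, +/-8 % for
utilities, +/-30 % for probabilities (clamped to [0, 1]) and 0-4 % for the
discount rate.  PSA families are gamma for costs and beta for probabilities
and utilities; point estimates of exactly 1 are kept fixed because a beta
distribution with mean 1 and positive variance does not exist.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "Parameter",
    "ParameterSet",
    "ParameterValidationError",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]

CATEGORIES = (
    "cost_initial",
    "cost_annual",
    "utility",
    "tree_probability",
    "transition_probability",
    "discount",
    "cycles",
)

_UNITS = {
    "cost_initial": "JPY",
    "cost_annual": "JPY_per_year",
    "utility": "utility",
    "tree_probability": "probability_per_year",
    "transition_probability": "probability_per_year",
    "discount": "percent",
    "cycles": "years",
}

#: category-wide relative DSA deviations
_DSA_DEVIATION = {
    "cost_initial": 0.20,
    "cost_annual": 0.20,
    "utility": 0.08,
    "tree_probability": 0.30,
    "transition_probability": 0.30,
}

#: discount-rate DSA range mandated by national guidance
DISCOUNT_DSA_RANGE = (0.0, 0.04)

#: PSA coefficient of variation (sd / mean) by category
PSA_CV = {
    "cost_initial": 0.10,
    "cost_annual": 0.10,
    "utility": 0.05,
    "tree_probability": 0.10,
    "transition_probability": 0.10,
}


class ParameterValidationError(ValueError):
    """A parameter file or value violates the schema or a range constraint."""


def _is_probability_like(category: str) -> bool:
    return category in ("utility", "tree_probability", "transition_probability")


def _default_dsa(category: str, value: float) -> tuple[float, float]:
    if category == "discount":
        lo, hi = DISCOUNT_DSA_RANGE
        return (min(lo, value), max(hi, value))
    if category == "cycles":
        return (value, value)
    d = _DSA_DEVIATION[category]
    lo, hi = value * (1 - d), value * (1 + d)
    if _is_probability_like(category):
        lo, hi = max(0.0, lo), min(1.0, hi)
    return (lo, hi)


def _default_psa_family(category: str, value: float) -> str:
    if category in ("cost_initial", "cost_annual"):
        return "gamma" if value > 0 else "fixed"
    if _is_probability_like(category):
        # beta moment-matching is degenerate at the boundary
        return "beta" if 0.0 < value < 1.0 else "fixed"
    return "fixed"


@dataclass
class Parameter:
    """A single model input with DSA range and PSA distribution family."""

    id: str
    value: float
    category: str
    units: str = ""
    dsa_low: float | None = None
    dsa_high: float | None = None
    psa_family: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ParameterValidationError(
                f"{self.id}: unknown category {self.category!r}")
        self.value = float(self.value)
        if not self.units:
            self.units = _UNITS[self.category]
        if self.dsa_low is None or self.dsa_high is None:
            self.dsa_low, self.dsa_high = _default_dsa(self.category, self.value)
        if self.psa_family is None:
            self.psa_family = _default_psa_family(self.category, self.value)
        self.validate()

    def validate(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ParameterValidationError(
                f"{self.id}: value must be a non-negative real, got {self.value}")
        if _is_probability_like(self.category) and not 0.0 <= self.value <= 1.0:
            raise ParameterValidationError(
                f"{self.id}: {self.category} must lie in [0, 1], got {self.value}")
        if self.category == "cycles" and self.value < 1:
            raise ParameterValidationError(
                f"{self.id}: cycle count must be >= 1, got {self.value}")
        if not self.dsa_low <= self.value <= self.dsa_high:
            raise ParameterValidationError(
                f"{self.id}: DSA range [{self.dsa_low}, {self.dsa_high}] "
                f"does not bracket the point estimate {self.value}")
        if self.psa_family not in ("beta", "gamma", "fixed"):
            raise ParameterValidationError(
                f"{self.id}: unknown PSA family {self.psa_family!r}")
        if self.psa_family == "beta" and not _is_probability_like(self.category):
            raise ParameterValidationError(
                f"{self.id}: beta PSA is only valid for probabilities/utilities")
        if self.psa_family == "gamma" and self.category not in (
                "cost_initial", "cost_annual"):
            raise ParameterValidationError(
                f"{self.id}: gamma PSA is only valid for costs")


def _defaults() -> list[Parameter]:
    P = Parameter
    return [
        # one-time diagnosis / treatment costs (JPY)
        P("screening_tests", 17_920, "cost_initial"),
        P("ct_avs", 570_620, "cost_initial"),
        P("hf_initial", 3_463_446, "cost_initial"),
        P("stroke_initial", 298_855, "cost_initial"),
        P("surgery", 996_710, "cost_initial"),
        P("rfa", 677_030, "cost_initial"),
        # annual medication / follow-up costs (JPY per year)
        P("drug_eht", 60_656, "cost_annual"),
        P("drug_success", 23_276, "cost_annual"),
        P("drug_pa_unoperated", 61_144, "cost_annual"),
        P("drug_partial_success", 61_144, "cost_annual"),
        P("hf_followup", 80_755, "cost_annual"),
        P("stroke_followup", 191_200, "cost_annual"),
        # state utilities
        P("u_eht", 1.0, "utility"),
        P("u_hf", 0.9, "utility"),
        P("u_stroke", 0.9, "utility"),
        # decision-tree branch probabilities
        P("prev_pa", 0.1, "tree_probability"),
        P("avs_success", 1.0, "tree_probability"),
        P("prev_apa_savs", 0.48, "tree_probability"),
        P("prev_apa_cavs", 0.461, "tree_probability"),
        P("p_rfa_given_apa", 0.085, "tree_probability"),
        P("surg_success_savs", 0.84, "tree_probability"),
        P("surg_success_cavs", 0.802, "tree_probability"),
        P("rfa_success", 1.0, "tree_probability"),
        P("drugfree_surgery", 0.44, "tree_probability"),
        P("drugfree_rfa", 1.0, "tree_probability"),
        # annual Markov transition probabilities
        P("cured_death", 0.00416, "transition_probability"),
        P("cured_hf", 0.0266, "transition_probability"),
        P("cured_stroke", 0.0011, "transition_probability"),
        P("pa_death", 0.0042, "transition_probability"),
        P("pa_hf", 0.0563, "transition_probability"),
        P("pa_stroke", 0.129, "transition_probability"),
        P("eht_death", 0.0042, "transition_probability"),
        P("eht_hf", 0.0266, "transition_probability"),
        P("eht_stroke", 0.034, "transition_probability"),
        P("hf_death", 0.0154, "transition_probability"),
        P("stroke_death", 0.00505, "transition_probability"),
        # discounting and horizons
        P("discount_rate", 0.02, "discount"),
        P("cycles_male", 32, "cycles"),
        P("cycles_female", 38, "cycles"),
    ]


#: competing-risk transition rows: hypertension exits per risk profile
RISK_PROFILE_ROWS: Mapping[str, tuple[str, str, str]] = {
    "cured": ("cured_death", "cured_hf", "cured_stroke"),
    "pa": ("pa_death", "pa_hf", "pa_stroke"),
    "eht": ("eht_death", "eht_hf", "eht_stroke"),
}


@dataclass
class ParameterSet:
    """Validated, immutable-by-convention collection of model parameters."""

    parameters: dict[str, Parameter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- access ---------------------------------------------------------
    def __getitem__(self, param_id: str) -> float:
        try:
            return self.parameters[param_id].value
        except KeyError:
            raise KeyError(f"unknown parameter id {param_id!r}") from None

    def __contains__(self, param_id: str) -> bool:
        return param_id in self.parameters

    def __iter__(self) -> Iterator[Parameter]:
        return iter(self.parameters.values())

    def get(self, param_id: str) -> Parameter:
        if param_id not in self.parameters:
            raise KeyError(f"unknown parameter id {param_id!r}")
        return self.parameters[param_id]

    def ids(self) -> list[str]:
        return list(self.parameters)

    def cycles(self, sex: str) -> int:
        if sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
        return int(round(self[f"cycles_{sex}"]))

    # -- derived --------------------------------------------------------
    def dsa_range(self, param_id: str) -> tuple[float, float]:
        p = self.get(param_id)
        return (p.dsa_low, p.dsa_high)

    def with_value(self, param_id: str, value: float) -> "ParameterSet":
        """New set with one value replaced; DSA range re-derived around it."""
        p = self.get(param_id)
        new = dataclasses.replace(p, value=value, dsa_low=None, dsa_high=None)
        params = dict(self.parameters)
        params[param_id] = new
        return ParameterSet(params)

    def with_values(self, values: Mapping[str, float]) -> "ParameterSet":
        params = dict(self.parameters)
        for pid, v in values.items():
            params[pid] = dataclasses.replace(
                self.get(pid), value=v, dsa_low=None, dsa_high=None)
        return ParameterSet(params)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        for p in self.parameters.values():
            p.validate()
        for profile, (d, h, s) in RISK_PROFILE_ROWS.items():
            if all(k in self.parameters for k in (d, h, s)):
                total = self[d] + self[h] + self[s]
                if total > 1.0 + 1e-12:
                    raise ParameterValidationError(
                        f"competing risks for profile {profile!r} sum to "
                        f"{total:.6f} > 1")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            p.id: {
                "value": p.value,
                "category": p.category,
                "units": p.units,
                "dsa_low": p.dsa_low,
                "dsa_high": p.dsa_high,
                "psa_family": p.psa_family,
            }
            for p in self
        }

    def to_frame(self) -> pd.DataFrame:
        """Resolved parameter table (id,value,units,dsa_low,dsa_high,psa_family)."""
        rows = [
            {"id": p.id, "value": p.value, "units": p.units,
             "dsa_low": p.dsa_low, "dsa_high": p.dsa_high,
             "psa_family": p.psa_family}
            for p in self
        ]
        return pd.DataFrame(rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def default_parameters() -> ParameterSet:
    """The published point estimates, exactly as printed."""
    return ParameterSet({p.id: p for p in _defaults()})


_ALLOWED_KEYS = {"value", "category", "units", "dsa_low", "dsa_high", "psa_family"}


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a YAML parameter file; omitted parameters fall back to defaults.

    The file maps parameter ids either to bare numbers (point-estimate
    override) or to mappings with any of ``value``, ``category``, ``units``,
    ``dsa_low``, ``dsa_high``, ``psa_family``.  Unknown ids and unknown keys
    raise :class:`ParameterValidationError`.
    """
    if path is None:
        path = resources.files("pa_cea").joinpath("data/default_parameters.yaml")
        raw = yaml.safe_load(path.read_text())
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterValidationError(
            "parameter file must be a mapping of id -> value or id -> fields")
    base = {p.id: p for p in _defaults()}
    for pid, entry in raw.items():
        if pid not in base:
            raise ParameterValidationError(f"unknown parameter id {pid!r}")
        if isinstance(entry, (int, float)):
            entry = {"value": float(entry)}
        if not isinstance(entry, dict):
            raise ParameterValidationError(
                f"{pid}: expected a number or mapping, got {type(entry).__name__}")
        extra = set(entry) - _ALLOWED_KEYS
        if extra:
            raise ParameterValidationError(
                f"{pid}: unknown field(s) {sorted(extra)}")
        merged = {
            "id": pid,
            "value": float(entry.get("value", base[pid].value)),
            "category": entry.get("category", base[pid].category),
            "units": entry.get("units", ""),
        }
        if "dsa_low" in entry or "dsa_high" in entry:
            merged["dsa_low"] = float(entry.get("dsa_low", base[pid].dsa_low))
            merged["dsa_high"] = float(entry.get("dsa_high", base[pid].dsa_high))
        if "psa_family" in entry:
            merged["psa_family"] = entry["psa_family"]
        try:
            base[pid] = Parameter(**merged)
        except ParameterValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise ParameterValidationError(f"{pid}: {exc}") from exc
    return ParameterSet(base)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write the full parameter set as YAML (round-trips losslessly)."""
    Path(path).write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=False))
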