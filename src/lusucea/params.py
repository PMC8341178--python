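"""Model inputs and input-derivation arithmetic.

Every quantity the cost-effectiveness model consumes — transition
probabilities, unit costs, utilities, run settings, sensitivity ranges and
probabilistic-analysis distribution assignments — lives in a single
validated :class:`ModelParameters` tree loaded from a YAML document. The
shipped ``data/base_case.yaml`` holds the published base case, so loading
it with no overrides reproduces the base-case analysis.

The module also implements the small pieces of derivation arithmetic the
model relies on: converting a pooled odds ratio into an intervention-arm
probability, converting a median survival into an annual mortality,
composing the per-day platelet-transfusion cost, and weighting the
procedure-cost mix.
"""

from __future__ import annotations

import copy
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

Arm = Literal["LUSU", "PT"]
ARMS: tuple[Arm, Arm] = ("LUSU", "PT")

__all__ = [
    "Arm",
    "ARMS",
    "EffectEstimate",
    "TransitionProbabilities",
    "CostInputs",
    "ProcedureMixEntry",
    "UtilityInputs",
    "Disutility",
    "ModelSettings",
    "ModelParameters",
    "odds_ratio_to_probability",
    "probability_to_odds_ratio",
    "median_survival_to_annual_mortality",
    "per_day_ae_risk",
    "pt_cost_per_day",
    "weighted_procedure_cost",
    "load_parameters",
    "default_parameters",
    "dump_parameters",
    "get_param",
    "set_param",
]


# ---------------------------------------------------------------------------
# derivation arithmetic


def odds_ratio_to_probability(reference_rate: float, odds_ratio: float) -> float:
    """Apply an odds ratio to a reference event rate.

    Returns ``o*OR / (1 + o*OR)`` with ``o`` the reference odds
    ``p/(1-p)``; this is the exact inverse of the odds-ratio definition, so
    recomputing the OR from (reference, result) recovers the input.
    """
    if not 0.0 < reference_rate < 1.0:
        raise ValueError(
            f"reference_rate must lie strictly in (0,1); got {reference_rate} "
            "(odds are degenerate at 0 or 1)"
        )
    if odds_ratio <= 0.0:
        raise ValueError(f"odds_ratio must be positive; got {odds_ratio}")
    odds = reference_rate / (1.0 - reference_rate) * odds_ratio
    return odds / (1.0 + odds)


def probability_to_odds_ratio(reference_rate: float, probability: float) -> float:
    """Odds ratio of ``probability`` relative to ``reference_rate``."""
    if not 0.0 < reference_rate < 1.0 or not 0.0 < probability < 1.0:
        raise ValueError("both rates must lie strictly in (0,1)")
    return (probability / (1.0 - probability)) / (reference_rate / (1.0 - reference_rate))


def median_survival_to_annual_mortality(median_survival_months: float) -> float:
    """Annual mortality from a median survival in months: ln(2)/median x 12."""
    if median_survival_months <= 0.0:
        raise ValueError("median survival must be positive")
    return math.log(2.0) / median_survival_months * 12.0


def per_day_ae_risk(risk_per_pack: float, packs_per_day: float) -> float:
    """Per transfusion-day allergic-reaction risk: per-pack risk x packs/day."""
    if risk_per_pack < 0.0 or packs_per_day < 0.0:
        raise ValueError("inputs must be non-negative")
    risk = risk_per_pack * packs_per_day
    if risk >= 1.0:
        raise ValueError(f"per-day risk {risk} is not a valid probability")
    return risk


def pt_cost_per_day(unit_cost: float, units_per_day: float, procedure_fee: float) -> float:
    """Daily platelet-transfusion cost: unit cost x units/day + procedure fee."""
    if min(unit_cost, units_per_day, procedure_fee) < 0.0:
        raise ValueError("cost components must be non-negative")
    return unit_cost * units_per_day + procedure_fee


def weighted_procedure_cost(mix: Iterable["ProcedureMixEntry"]) -> float:
    """Share-weighted mean procedure cost, with shares renormalised.

    The published share column sums to 100.1%, so shares are divided by
    their own total; the result is invariant to rescaling all shares.
    """
    entries = list(mix)
    if not entries:
        raise ValueError("procedure mix must contain at least one entry")
    total = sum(e.share for e in entries)
    if total <= 0.0:
        raise ValueError("procedure-mix shares must have a positive sum")
    return sum(e.share * e.cost for e in entries) / total


# ---------------------------------------------------------------------------
# domain types


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EffectEstimate(_Model):
    """A pooled odds ratio with its 95% confidence interval."""

    odds_ratio: float = Field(gt=0)
    ci_lower: float = Field(gt=0)
    ci_upper: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "EffectEstimate":
        if not self.ci_lower <= self.odds_ratio <= self.ci_upper:
            raise ValueError(
                f"CI must bracket the point estimate: {self.ci_lower} <= "
                f"{self.odds_ratio} <= {self.ci_upper} fails"
            )
        return self

    @property
    def log_sigma(self) -> float:
        """SE of the log odds ratio implied by the Wald 95% CI."""
        return (math.log(self.ci_upper) - math.log(self.ci_lower)) / (2.0 * 1.959963984540054)


Probability = Field(ge=0.0, le=1.0)


class ByStatus(_Model):
    """A probability keyed by prior-transfusion status."""

    received: float = Probability
    none: float = Probability


class ByArm(_Model):
    LUSU: ByStatus
    PT: ByStatus

    def get(self, arm: Arm, received_prior_pt: bool) -> float:
        by = getattr(self, arm)
        return by.received if received_prior_pt else by.none


class TransitionProbabilities(_Model):
    p_prePT_PT: float = Probability
    pooled_prePT_rate: float = Probability
    or_prePT: EffectEstimate
    p_bleed_PT: float = Probability
    or_bleed: EffectEstimate
    p_noproc: ByArm
    p_rescue: ByArm
    p_thrombosis: float = Probability
    ae_risk_per_pack: float = Probability
    packs_per_day: float = Field(gt=0)
    p_death_allergic: float = Probability
    p_death_bleed: float = Probability
    annual_mortality: dict[str, float]
    cp_weights: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "TransitionProbabilities":
        for cls, m in self.annual_mortality.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"annual_mortality[{cls}]={m} outside [0,1]")
        if set(self.cp_weights) != set(self.annual_mortality):
            raise ValueError("cp_weights and annual_mortality must share Child-Pugh classes")
        w = sum(self.cp_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"Child-Pugh weights sum to {w}, not 1")
        if any(v < 0 for v in self.cp_weights.values()):
            raise ValueError("Child-Pugh weights must be non-negative")
        return self

    def p_prePT(self, arm: Arm) -> float:
        """Probability of requiring pre-procedure transfusion, by arm."""
        if arm == "PT":
            return self.p_prePT_PT
        return odds_ratio_to_probability(self.pooled_prePT_rate, self.or_prePT.odds_ratio)

    def p_bleed(self, arm: Arm) -> float:
        """Probability of post-procedure bleeding, by arm."""
        if arm == "PT":
            return self.p_bleed_PT
        return odds_ratio_to_probability(self.p_bleed_PT, self.or_bleed.odds_ratio)

    @property
    def ae_risk_per_day(self) -> float:
        return per_day_ae_risk(self.ae_risk_per_pack, self.packs_per_day)


class ProcedureMixEntry(_Model):
    name: str
    share: float = Field(ge=0.0, le=1.0)
    cost: float = Field(ge=0.0)


class CostInputs(_Model):
    pt_cost_per_unit: float = Field(ge=0)
    pt_units_per_day: float = Field(gt=0)
    pt_procedure_fee: float = Field(ge=0)
    pt_days: dict[Arm, float]
    lusu_tablets: float = Field(gt=0)
    lusu_price_per_tablet: float = Field(ge=0)
    delay_extra_days: int = Field(ge=0)
    hosp_cost_per_day: float = Field(ge=0)
    rescue_transfusion_per_day: float = Field(ge=0)
    rescue_ae_component: float = Field(ge=0)
    thrombosis_treatment_cost: float = Field(ge=0)
    allergic_treatment_cost: float = Field(ge=0)
    procedure_mix: list[ProcedureMixEntry]

    @field_validator("pt_days")
    @classmethod
    def _days(cls, v: dict[Arm, float]) -> dict[Arm, float]:
        if set(v) != set(ARMS):
            raise ValueError("pt_days must be given for both arms")
        if any(d < 0 for d in v.values()):
            raise ValueError("pt_days must be non-negative")
        return v

    @property
    def pt_day_cost(self) -> float:
        return pt_cost_per_day(self.pt_cost_per_unit, self.pt_units_per_day, self.pt_procedure_fee)

    @property
    def rescue_cost(self) -> float:
        return self.rescue_transfusion_per_day + self.rescue_ae_component

    @property
    def delay_cost(self) -> float:
        return self.delay_extra_days * self.hosp_cost_per_day

    @property
    def procedure_cost(self) -> float:
        return weighted_procedure_cost(self.procedure_mix)


class Disutility(_Model):
    """A temporary utility decrement (stored as a positive magnitude)."""

    decrement: float = Field(ge=0.0, le=1.0)
    duration_weeks: float = Field(gt=0.0)


class UtilityInputs(_Model):
    u_base: float = Field(ge=0.0, le=1.0)
    du_thrombosis: Disutility
    du_allergic: Disutility
    du_bleed: Disutility
    du_delay: Disutility
    reg_intercept: float
    reg_male: float
    reg_age: float


class ModelSettings(_Model):
    discount_rate: float = Field(ge=0.0, lt=1.0)
    horizon_years: float = Field(gt=0.0)
    tree_horizon_days: int = Field(gt=0)
    start_age: float = Field(ge=0.0)
    male_fraction: float = Field(ge=0.0, le=1.0)
    wtp_threshold: float = Field(ge=0.0)
    markov_cycle: Literal["annual"] = "annual"
    psa_iterations: int = Field(gt=0)
    rng_seed: int
    days_per_year: float = 365.25
    age_adjust_utility: bool = False

    @model_validator(mode="after")
    def _horizon(self) -> "ModelSettings":
        if self.horizon_years < self.tree_horizon_days / self.days_per_year:
            raise ValueError("horizon_years must cover at least the tree phase")
        return self


class ModelParameters(_Model):
    transitions: TransitionProbabilities
    costs: CostInputs
    utilities: UtilityInputs
    settings: ModelSettings
    owsa_ranges: dict[str, tuple[float, float]] = {}
    psa_spec: dict[str, dict] = {}

    @model_validator(mode="after")
    def _ranges_bracket_base(self) -> "ModelParameters":
        for pid, (lo, hi) in self.owsa_ranges.items():
            if lo > hi:
                raise ValueError(f"owsa_ranges[{pid}]: lower {lo} exceeds upper {hi}")
            base = get_param(self, pid)
            if not lo <= base <= hi:
                raise ValueError(
                    f"owsa_ranges[{pid}]: base value {base} outside [{lo}, {hi}]"
                )
        return self

    def copy_deep(self) -> "ModelParameters":
        """Deep copy for scenario/sensitivity overrides (not re-validated)."""
        return self.model_copy(deep=True)


# ---------------------------------------------------------------------------
# parameter addressing (shared by the one-way and probabilistic analyses)

# Most ids are dotted paths into the tree relative to the section that owns
# them; a few are virtual quantities with bespoke accessors.


def _resolve(params: ModelParameters, pid: str):
    """Return (owner, attribute-or-key) for a dotted parameter id."""
    if pid.startswith("procedure_cost."):
        idx = int(pid.split(".", 1)[1])
        return params.costs.procedure_mix[idx], "cost"
    roots = {
        "or_prePT": ("transitions", "or_prePT.odds_ratio"),
        "or_bleed": ("transitions", "or_bleed.odds_ratio"),
        "p_bleed_PT": ("transitions", "p_bleed_PT"),
        "p_thrombosis": ("transitions", "p_thrombosis"),
        "p_death_allergic": ("transitions", "p_death_allergic"),
        "p_death_bleed": ("transitions", "p_death_bleed"),
        "pt_units_per_day": ("costs", "pt_units_per_day"),
        "pt_procedure_fee": ("costs", "pt_procedure_fee"),
        "hosp_cost_per_day": ("costs", "hosp_cost_per_day"),
        "thrombosis_treatment_cost": ("costs", "thrombosis_treatment_cost"),
        "allergic_treatment_cost": ("costs", "allergic_treatment_cost"),
        "u_base": ("utilities", "u_base"),
        "du_thrombosis": ("utilities", "du_thrombosis.decrement"),
        "du_allergic": ("utilities", "du_allergic.decrement"),
        "du_bleed": ("utilities", "du_bleed.decrement"),
    }
    if pid in roots:
        section, path = roots[pid]
        obj = getattr(params, section)
    elif pid.startswith(("p_noproc.", "p_rescue.")):
        obj, path = params.transitions, pid
    elif pid.startswith("pt_days."):
        obj, path = params.costs, pid
    else:
        raise KeyError(f"unknown parameter id: {pid!r}")
    *steps, last = path.split(".")
    for step in steps:
        obj = obj[step] if isinstance(obj, dict) else getattr(obj, step)
    return obj, last


def get_param(params: ModelParameters, pid: str) -> float:
    """Read a scalar model input by parameter id."""
    if pid == "p_allergic_per_day":
        return params.transitions.ae_risk_per_day
    owner, last = _resolve(params, pid)
    return owner[last] if isinstance(owner, dict) else getattr(owner, last)


def set_param(params: ModelParameters, pid: str, value: float) -> None:
    """Set a scalar model input by parameter id, in place.

    Assignment bypasses cross-field re-validation on purpose: sensitivity
    draws may legitimately leave a point estimate outside its loaded CI.
    """
    if pid == "p_allergic_per_day":
        params.transitions.ae_risk_per_pack = value / params.transitions.packs_per_day
        return
    owner, last = _resolve(params, pid)
    if isinstance(owner, dict):
        owner[last] = value
    else:
        setattr(owner, last, value)


# ---------------------------------------------------------------------------
# loading


def _default_config_path() -> Path:
    return Path(str(resources.files("lusucea").joinpath("data/base_case.yaml")))


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_parameters(
    source: str | Path | Mapping | None = None,
    overrides: Mapping | None = None,
) -> ModelParameters:
    """Load and validate a :class:`ModelParameters` tree.

    ``source`` may be a YAML file path, an already-parsed mapping, or
    ``None`` for the shipped base case. ``overrides`` is deep-merged on top,
    so an empty override section reproduces the base case exactly.
    """
    if source is None:
        source = _default_config_path()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    if overrides:
        doc = _deep_merge(doc, overrides)
    return ModelParameters.model_validate(doc)


def default_parameters() -> ModelParameters:
    """The shipped published base case."""
    return load_parameters(None)


def dump_parameters(params: ModelParameters) -> str:
    """Serialise a parameter set back to canonical YAML."""
    return yaml.safe_dump(params.model_dump(mode="json"), sort_keys=True)
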