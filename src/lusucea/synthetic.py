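"""Synthetic trial tables and parameter perturbations for testing.

The pooled odds ratios the model consumes come from two placebo-controlled
two-arm trials with binary endpoints. :func:`generate_trial` emulates such
a trial: the control arm has a stated event risk, the treatment arm the
risk implied by a true odds ratio, and events are drawn binomially. This
gives the meta-analysis stage a ground truth against which recovery and
confidence-interval coverage can be measured.

:func:`generate_parameter_perturbation` jitters a full parameter set
within each quantity's legal support (logit scale for probabilities,
multiplicative for costs and durations), for property-based tests of the
model engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .meta import Study2x2
from .params import ModelParameters, get_param, odds_ratio_to_probability, set_param

__all__ = ["TrialSpec", "generate_trial", "generate_trial_pair", "generate_parameter_perturbation"]


@dataclass(frozen=True)
class TrialSpec:
    """Design of one synthetic two-arm trial."""

    n_treat: int = 150
    n_ctrl: int = 150
    control_risk: float = 0.8571
    true_or: float = 0.04
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_treat < 1 or self.n_ctrl < 1:
            raise ValueError("arm sizes must be at least 1")
        if not 0.0 < self.control_risk < 1.0:
            raise ValueError("control_risk must lie strictly in (0,1)")
        if self.true_or <= 0.0:
            raise ValueError("true_or must be positive")


def generate_trial(spec: TrialSpec, rng: np.random.Generator | None = None) -> Study2x2:
    """Draw one reproducible 2x2 trial table."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    risk_treat = odds_ratio_to_probability(spec.control_risk, spec.true_or)
    return Study2x2(
        label=spec.label,
        events_treat=int(rng.binomial(spec.n_treat, risk_treat)),
        n_treat=spec.n_treat,
        events_ctrl=int(rng.binomial(spec.n_ctrl, spec.control_risk)),
        n_ctrl=spec.n_ctrl,
    )


def generate_trial_pair(spec: TrialSpec) -> list[Study2x2]:
    """Two independent trials of the same design (one seeded generator,
    split into one stream per trial)."""
    streams = np.random.default_rng(spec.seed).spawn(2)
    return [
        generate_trial(
            TrialSpec(
                n_treat=spec.n_treat, n_ctrl=spec.n_ctrl,
                control_risk=spec.control_risk, true_or=spec.true_or,
                seed=spec.seed, label=f"{spec.label}-{i + 1}",
            ),
            rng=stream,
        )
        for i, stream in enumerate(streams)
    ]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# ids of every scalar a perturbation touches; probabilities jitter on the
# logit scale, the rest multiplicatively
_PROB_IDS = [
    "p_bleed_PT", "p_thrombosis", "p_death_allergic", "p_death_bleed",
    "p_noproc.PT.received", "p_noproc.PT.none",
    "p_noproc.LUSU.received", "p_noproc.LUSU.none",
    "p_rescue.PT.received", "p_rescue.LUSU.none",
    "u_base", "du_thrombosis", "du_allergic", "du_bleed",
]
_SCALE_IDS = [
    "or_prePT", "or_bleed",
    "pt_units_per_day", "pt_procedure_fee", "hosp_cost_per_day",
    "thrombosis_treatment_cost", "allergic_treatment_cost",
    "pt_days.LUSU", "pt_days.PT",
]


def generate_parameter_perturbation(
    base: ModelParameters, scale: float, seed: int
) -> ModelParameters:
    """A valid parameter set jittered around ``base``.

    ``scale`` in [0, 0.5] controls the jitter magnitude; 0 returns the
    base unchanged. Every produced quantity respects its support, so the
    result always passes parameter validation.
    """
    if not 0.0 <= scale <= 0.5:
        raise ValueError("scale must lie in [0, 0.5]")
    params = base.copy_deep()
    if scale == 0.0:
        return params
    rng = np.random.default_rng(seed)
    for pid in _PROB_IDS:
        p = get_param(params, pid)
        if 0.0 < p < 1.0:
            set_param(params, pid, _expit(_logit(p) + rng.normal(0.0, scale)))
    for pid in _SCALE_IDS:
        set_param(params, pid, get_param(params, pid) * math.exp(rng.normal(0.0, scale)))
    # keep the effect-estimate CIs bracketing the jittered point estimates
    for est in (params.transitions.or_prePT, params.transitions.or_bleed):
        est.ci_lower = min(est.ci_lower, est.odds_ratio)
        est.ci_upper = max(est.ci_upper, est.odds_ratio)
    # widen one-way ranges so they still bracket the jittered base values
    for pid, (lo, hi) in params.owsa_ranges.items():
        v = get_param(params, pid)
        params.owsa_ranges[pid] = (min(lo, v), max(hi, v))
    return params
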