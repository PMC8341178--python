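"""Strategy totals, increments, ICER/dominance, and the scenario runner.

A strategy's lifetime cost is its tree-phase cost (the model attaches no
costs to the Markov phase); its lifetime QALYs are the tree-phase QALYs
plus the tree survival probability times the discounted per-survivor
QALYs of the lifetime phase. Increments are always lusutrombopag minus
platelet transfusion.

The ICER is reported only in the trade-off quadrants; elsewhere the
comparison is labelled by dominance, matching how such results are
conventionally tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .markov import run_markov
from .params import ARMS, Arm, ModelParameters
from .tree import ArmTreeResult, evaluate_tree

ScenarioTag = Literal["base", "A", "B", "C"]
SCENARIOS: tuple[ScenarioTag, ...] = ("base", "A", "B", "C")

SCENARIO_NOTES = {
    "base": "published base case",
    "A": "pre-procedure transfusion lasts 1 day in both arms",
    "B": "PT-arm pre-procedure transfusion rate set to the pooled 85.71%",
    "C": "time horizon restricted to the 35-day tree phase",
}

__all__ = [
    "ScenarioTag",
    "SCENARIOS",
    "SCENARIO_NOTES",
    "StrategyOutcome",
    "CEAResult",
    "evaluate_strategy",
    "compute_icer",
    "net_monetary_benefit",
    "apply_scenario",
    "run_scenario",
    "run_comparison",
]


@dataclass
class StrategyOutcome:
    """Lifetime totals for one arm, with the phase results that built them."""

    arm: Arm
    cost: float
    qaly: float
    tree: ArmTreeResult
    markov_qaly_per_survivor: float


@dataclass
class CEAResult:
    """Two-strategy comparison: totals, increments, verdict, NMB."""

    scenario: str
    outcomes: dict[Arm, StrategyOutcome]
    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str
    nmb_at_threshold: float
    threshold: float
    notes: str = field(default="")


def evaluate_strategy(arm: Arm, params: ModelParameters) -> StrategyOutcome:
    """Tree phase plus (when the horizon allows) the lifetime phase."""
    tree_res = evaluate_tree(arm, params)
    st = params.settings
    if st.horizon_years >= 1.0:
        life = run_markov(tree_res.survival_prob, params)
        markov_q = life.discounted_qaly_per_survivor
    else:
        markov_q = 0.0
    return StrategyOutcome(
        arm=arm,
        cost=tree_res.expected_cost,
        qaly=tree_res.expected_qaly + tree_res.survival_prob * markov_q,
        tree=tree_res,
        markov_qaly_per_survivor=markov_q,
    )


def compute_icer(
    cost_new: float, cost_ref: float, qaly_new: float, qaly_ref: float
) -> tuple[float, float, float | None, str]:
    """Increments and verdict for a new strategy against a reference.

    Returns ``(delta_cost, delta_qaly, icer, label)``. The ICER value is
    populated only in the north-east quadrant (more costly, more
    effective); all other sign combinations carry a dominance-style label.
    """
    dc = cost_new - cost_ref
    dq = qaly_new - qaly_ref
    icer: float | None = None
    if dq > 0 and dc < 0:
        label = "dominant"
    elif dq < 0 and dc > 0:
        label = "dominated"
    elif dq > 0 and dc > 0:
        icer = dc / dq
        label = "icer"
    elif dq < 0 and dc < 0:
        label = "less_costly_less_effective"
    elif dq == 0 and dc != 0:
        label = "dominant" if dc < 0 else "dominated"
    else:
        label = "equivalent"
    return dc, dq, icer, label


def net_monetary_benefit(delta_qaly: float, delta_cost: float, threshold: float) -> float:
    """NMB = threshold x incremental QALYs - incremental cost."""
    if threshold < 0:
        raise ValueError("willingness-to-pay threshold must be non-negative")
    return threshold * delta_qaly - delta_cost


def apply_scenario(tag: ScenarioTag, params: ModelParameters) -> ModelParameters:
    """Return a parameter copy with exactly one scenario override applied."""
    if tag not in SCENARIOS:
        raise ValueError(f"unknown scenario {tag!r}; expected one of {SCENARIOS}")
    p = params.copy_deep()
    if tag == "A":
        p.costs.pt_days = {"LUSU": 1.0, "PT": 1.0}
    elif tag == "B":
        p.transitions.p_prePT_PT = 0.8571
    elif tag == "C":
        p.settings.horizon_years = p.settings.tree_horizon_days / p.settings.days_per_year
    return p


def run_comparison(params: ModelParameters, scenario: str = "base") -> CEAResult:
    """Evaluate both strategies under ``params`` and compare them."""
    outcomes = {arm: evaluate_strategy(arm, params) for arm in ARMS}
    dc, dq, icer, label = compute_icer(
        outcomes["LUSU"].cost, outcomes["PT"].cost,
        outcomes["LUSU"].qaly, outcomes["PT"].qaly,
    )
    threshold = params.settings.wtp_threshold
    return CEAResult(
        scenario=scenario,
        outcomes=outcomes,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        label=label,
        nmb_at_threshold=net_monetary_benefit(dq, dc, threshold),
        threshold=threshold,
        notes=SCENARIO_NOTES.get(scenario, ""),
    )


def run_scenario(tag: ScenarioTag, params: ModelParameters) -> CEAResult:
    """Run one of the published analyses: base case or scenario A/B/C."""
    return run_comparison(apply_scenario(tag, params), scenario=tag)
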