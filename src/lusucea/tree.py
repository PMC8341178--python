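"""The 35-day procedure-period decision tree.

Each strategy arm is evaluated in expectation over the joint distribution
of the short-term events: pre-procedure platelet transfusion, delay of the
planned procedure (delayed patients are rescheduled and still undergo it,
at the cost of extra hospital days), post-procedure bleeding, rescue
transfusion after bleeding, treatment-specific adverse events (thrombosis
under lusutrombopag; severe allergic reaction per transfusion-exposure
day), and death from bleeding or from an allergic reaction.

Conventions:

* All patients accrue the share-weighted procedure cost; the LUSU arm
  accrues the drug course; patients transfused before the procedure accrue
  the per-day transfusion cost times the arm's mean transfusion days.
* Rescue is one transfusion day, costed as the per-day rescue transfusion
  cost plus the small allergic-reaction component.
* The allergic-reaction probability is linear in transfusion-exposure
  days (prior-transfusion days plus one rescue day where rescued), using
  the unrounded per-day risk.
* Deaths do not truncate within-tree QALYs (the 35-day QALY mass is
  small); they remove the patient from the lifetime phase. Allergic-
  reaction survivors accrue the treatment cost and the 4-week disutility;
  thrombosis carries no mortality.
* No discounting inside the 35-day horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import Arm, ModelParameters

__all__ = ["ArmTreeResult", "evaluate_tree", "tree_death_probability"]


@dataclass
class ArmTreeResult:
    """Expected 35-day cost, QALYs and survival for one strategy arm."""

    arm: Arm
    expected_cost: float
    expected_qaly: float
    survival_prob: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)
    qaly_decrements: dict[str, float] = field(default_factory=dict)


def evaluate_tree(arm: Arm, params: ModelParameters) -> ArmTreeResult:
    """Expected tree-phase outcomes for ``arm`` under ``params``."""
    tr, co, ut, st = params.transitions, params.costs, params.utilities, params.settings

    p_pre = tr.p_prePT(arm)
    p_bleed = tr.p_bleed(arm)
    ae_day = tr.ae_risk_per_day
    d_bleed = tr.p_death_bleed
    d_all = tr.p_death_allergic
    pt_day_cost = co.pt_day_cost
    pt_days = co.pt_days[arm]
    week = 7.0 / st.days_per_year

    cost = {
        "procedure": co.procedure_cost,
        "lusu_drug": 0.0,
        "prior_pt": 0.0,
        "delay": 0.0,
        "rescue": 0.0,
        "thrombosis_ae": 0.0,
        "allergic_ae": 0.0,
    }
    decrement = {"bleeding": 0.0, "thrombosis": 0.0, "allergic": 0.0}
    p_death = 0.0

    if arm == "LUSU":
        cost["lusu_drug"] = co.lusu_tablets * co.lusu_price_per_tablet
        cost["thrombosis_ae"] = tr.p_thrombosis * co.thrombosis_treatment_cost
        decrement["thrombosis"] = (
            tr.p_thrombosis * ut.du_thrombosis.decrement * ut.du_thrombosis.duration_weeks * week
        )

    # enumerate the discrete pathway skeleton: prior transfusion x delay x
    # bleeding x rescue; allergic reaction and deaths are expanded
    # analytically within each pathway
    for prior, p_prior in ((True, p_pre), (False, 1.0 - p_pre)):
        if p_prior == 0.0:
            continue
        p_delay = tr.p_noproc.get(arm, prior)
        p_resc = tr.p_rescue.get(arm, prior)
        if prior:
            cost["prior_pt"] += p_prior * pt_day_cost * pt_days
        cost["delay"] += p_prior * p_delay * co.delay_cost
        for bleed, p_b in ((True, p_bleed), (False, 1.0 - p_bleed)):
            for rescue, p_r in ((True, p_resc), (False, 1.0 - p_resc)):
                if bleed is False and rescue:
                    continue  # rescue only follows bleeding
                p_path = p_prior * p_b * (p_r if bleed else 1.0)
                if p_path == 0.0:
                    continue
                if bleed and rescue:
                    cost["rescue"] += p_path * co.rescue_cost
                exposure = (pt_days if prior else 0.0) + (1.0 if bleed and rescue else 0.0)
                p_allergic = exposure * ae_day
                cost["allergic_ae"] += p_path * p_allergic * (1.0 - d_all) * co.allergic_treatment_cost
                decrement["allergic"] += (
                    p_path
                    * p_allergic
                    * (1.0 - d_all)
                    * ut.du_allergic.decrement
                    * ut.du_allergic.duration_weeks
                    * week
                )
                if bleed:
                    decrement["bleeding"] += (
                        p_path * ut.du_bleed.decrement * ut.du_bleed.duration_weeks * week
                    )
                # independent competing deaths within the pathway
                p_die = (d_bleed if bleed else 0.0) + p_allergic * d_all
                if bleed:
                    p_die -= d_bleed * p_allergic * d_all
                p_death += p_path * p_die

    qaly = ut.u_base * st.tree_horizon_days / st.days_per_year - sum(decrement.values())
    result = ArmTreeResult(
        arm=arm,
        expected_cost=sum(cost.values()),
        expected_qaly=qaly,
        survival_prob=1.0 - p_death,
        cost_breakdown=cost,
        qaly_decrements=decrement,
    )
    _validate(result)
    return result


def tree_death_probability(arm: Arm, params: ModelParameters) -> float:
    """Probability of dying during the 35-day tree phase."""
    return 1.0 - evaluate_tree(arm, params).survival_prob


def _validate(res: ArmTreeResult) -> None:
    if not 0.0 < res.survival_prob <= 1.0:
        raise ValueError(f"tree survival probability {res.survival_prob} outside (0,1]")
    drift = abs(res.expected_cost - sum(res.cost_breakdown.values()))
    if drift > 1e-6:
        raise ValueError(f"cost breakdown drifts from total by {drift}")
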