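"""Lifetime alive/dead Markov phase for tree survivors.

Tree survivors enter an annual-cycle cohort model stratified by Child-Pugh
class. Each class keeps its printed annual mortality; because the strata
are tracked separately, the cohort's effective mortality is the
membership-weighted average of the class-specific rates at every cycle
(the surviving cohort drifts toward the milder class over time). Cohort
membership is counted at cycle start with no half-cycle correction, and
each cycle contributes one year at the cycle's utility, discounted by
(1+r)^-t with the first Markov year undiscounted.

The health-state utility is the chronic-liver-disease baseline (0.808 in
the base case). An optional age adjustment scales it by the ratio of the
general-population utility regression at the cohort's current age to its
value at the start age; see docs/methods.md for why the base
configuration leaves this off.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .params import ModelParameters

__all__ = [
    "MarkovTrace",
    "LifetimeResult",
    "general_population_utility",
    "cld_utility_at_age",
    "run_markov",
]


@dataclass
class LifetimeResult:
    """Discounted QALYs accrued after the tree phase, per survivor."""

    discounted_qaly_per_survivor: float
    trace: pd.DataFrame  # one row per cycle


MarkovTrace = pd.DataFrame


def general_population_utility(
    age: float, male_fraction: float, params: ModelParameters | None = None
) -> float:
    """General-population utility from the published linear regression.

    ``intercept + b_male * male_fraction + b_age * age``; the male share is
    a fraction in [0, 1]. The raw linear form is returned (clipping to the
    utility scale happens where the value is applied).
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if not 0.0 <= male_fraction <= 1.0:
        raise ValueError("male_fraction must lie in [0,1]")
    if params is None:
        b0, bm, ba = 0.9978786, 0.0218333, -0.002153
    else:
        ut = params.utilities
        b0, bm, ba = ut.reg_intercept, ut.reg_male, ut.reg_age
    return b0 + bm * male_fraction + ba * age


def cld_utility_at_age(age: float, params: ModelParameters) -> float:
    """Age-adjusted utility of the chronic-liver-disease cohort.

    The baseline utility is scaled by the general-population utility at
    ``age`` relative to the start age, then clipped to [0, 1].
    """
    st, ut = params.settings, params.utilities
    if age < st.start_age:
        raise ValueError(f"age {age} precedes the cohort start age {st.start_age}")
    ref = general_population_utility(st.start_age, st.male_fraction, params)
    if ref <= 0:
        raise ValueError("general-population utility at start age must be positive")
    u = ut.u_base * general_population_utility(age, st.male_fraction, params) / ref
    return min(1.0, max(0.0, u))


def _cycle_utility(age: float, params: ModelParameters) -> float:
    if params.settings.age_adjust_utility:
        return cld_utility_at_age(age, params)
    return params.utilities.u_base


def run_markov(survivor_fraction: float, params: ModelParameters) -> LifetimeResult:
    """Run the lifetime phase and return discounted QALYs per survivor.

    ``survivor_fraction`` scales the trace only; the per-survivor QALY
    total is independent of it.
    """
    if not 0.0 <= survivor_fraction <= 1.0:
        raise ValueError("survivor_fraction must lie in [0,1]")
    st, tr = params.settings, params.transitions
    n_cycles = int(st.horizon_years + 1e-9)
    if n_cycles < 1:
        raise ValueError("horizon shorter than one Markov cycle")

    classes = sorted(tr.cp_weights)
    alive = {c: tr.cp_weights[c] for c in classes}  # per-survivor shares
    rows = []
    total = 0.0
    for t in range(n_cycles):
        age = st.start_age + t
        u = _cycle_utility(age, params)
        disc = (1.0 + st.discount_rate) ** (-t)
        frac = sum(alive.values())
        dq = frac * u * disc
        total += dq
        rows.append(
            {"cycle": t, "age": age,
             **{f"alive_{c}": survivor_fraction * alive[c] for c in classes},
             "alive_total": survivor_fraction * frac,
             "utility": u, "discount": disc,
             "discounted_qaly": survivor_fraction * dq}
        )
        for c in classes:
            alive[c] *= 1.0 - tr.annual_mortality[c]

    trace = pd.DataFrame(rows)
    return LifetimeResult(discounted_qaly_per_survivor=total, trace=trace)
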