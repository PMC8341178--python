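"""Base-case analysis and the three published scenarios.

Evaluates both strategies — lusutrombopag (LUSU) and prophylactic
platelet transfusion (PT) — over the 35-day decision tree plus the
50-year Markov phase, then prints lifetime cost (JPY), QALYs, the
increments, and the verdict for the base case and scenarios A-C.
A negative incremental cost together with a positive incremental QALY
means LUSU is *dominant*: cheaper and more effective.
"""

from lusucea import default_parameters, run_scenario
from lusucea.engine import SCENARIO_NOTES

params = default_parameters()

for tag in ("base", "A", "B", "C"):
    res = run_scenario(tag, params)
    print(f"\nScenario {tag}: {SCENARIO_NOTES[tag]}")
    for arm in ("LUSU", "PT"):
        o = res.outcomes[arm]
        print(f"  {arm:<5} cost {o.cost:>12,.0f} JPY   QALYs {o.qaly:.4f}")
    verdict = res.label if res.icer is None else f"ICER {res.icer:,.0f} JPY/QALY"
    print(f"  increment: {res.delta_cost:+,.0f} JPY, {res.delta_qaly:+.4f} QALYs -> {verdict}")
    print(f"  net monetary benefit at 5M JPY/QALY: {res.nmb_at_threshold:,.0f} JPY")
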