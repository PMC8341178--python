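# lusucea

Cost-effectiveness model of **lusutrombopag (LUSU)** versus prophylactic
**platelet transfusion (PT)** for severe thrombocytopenia (platelet count
< 50×10⁹/L) in chronic liver disease patients who need a planned invasive
procedure, from the Japanese public healthcare payer's perspective.

The package is for health-economics analysts and methodologists who want a
tested, scriptable reimplementation of this published decision model — to
reproduce its results, probe its assumptions, or reuse its components
(odds-ratio derivations, decision tree, Markov cohort, tornado and
probabilistic sensitivity analyses, DerSimonian–Laird pooling) on modified
inputs.

## The model

A **35-day decision tree** covers the procedure period. For each arm it
tracks: pre-procedure transfusion (PT arm: 100%; LUSU arm: derived by
applying the pooled odds ratio OR = 0.04 to the pooled reference rate
85.71% via the odds transform, giving 19.35%), procedure delay (4 extra
hospital days), post-procedure bleeding (PT 33.33%; LUSU via OR = 0.44 →
18.03%), rescue transfusion, severe thrombosis (LUSU only, 1.56%), severe
allergic reaction (0.0468% per transfusion-exposure day), and death from
bleeding (0.83%) or allergic reaction (10%). Costs (drug course, per-day
transfusion, weighted procedure mix, delay, rescue, adverse-event
treatment) all accrue in the tree; QALYs are the baseline utility 0.808
over 35/365.25 years minus probability-weighted disutility×duration terms.

Tree survivors enter an **annual-cycle alive/dead Markov cohort** over a
50-year horizon, stratified by Child–Pugh class (A/B weighted 52/48 with
annual mortality 0.099/0.139), utility 0.808, and 2% annual discounting.

Outputs per comparison: lifetime cost and QALYs per arm, increments
ΔC and ΔQ, the ICER ΔC/ΔQ or a dominance verdict, and the net monetary
benefit NMB = λ·ΔQ − ΔC at the willingness-to-pay threshold
λ = 5,000,000 JPY/QALY.

Uncertainty is handled two ways: a **one-way sensitivity analysis** (each
parameter alone pushed to its published range; parameters ranked by NMB
spread — the tornado diagram) and a **probabilistic sensitivity analysis**
(1000 Monte-Carlo draws: lognormal odds ratios, beta probabilities and
utilities, zero-truncated normal costs; summarised as the probability of
dominance and the cost-effectiveness acceptability curve).

## Worked example

```python
from lusucea import default_parameters, run_scenario

res = run_scenario("base", default_parameters())
for arm in ("LUSU", "PT"):
    o = res.outcomes[arm]
    print(f"{arm:<5} cost {o.cost:>12,.0f} JPY   QALYs {o.qaly:.4f}")
print(f"increment: {res.delta_cost:+,.0f} JPY, {res.delta_qaly:+.4f} QALYs -> {res.label}")
```

prints

```
LUSU  cost    2,377,764 JPY   QALYs 6.1484
PT    cost    2,379,987 JPY   QALYs 6.1393
increment: -2,223 JPY, +0.0092 QALYs -> dominant
```

LUSU costs slightly less over a lifetime (the avoided transfusions,
delays and rescue therapy more than offset the drug price) and yields
slightly more QALYs (less bleeding, fewer bleeding deaths), so it
*dominates* platelet transfusion: no ICER is reported. The `examples/`
directory has one short script per capability — scenarios, tornado,
probabilistic analysis, meta-analytic pooling — each printing and
explaining its numbers.

The same analyses are available from the shell:

```bash
lusucea run --scenario base          # or A / B / C
lusucea owsa --top 10
lusucea psa --n 1000 --seed 20210626
lusucea synth --n-pairs 2 --seed 3 > studies.csv && lusucea meta studies.csv
```

All inputs live in `src/lusucea/data/base_case.yaml`; pass `--params` (or
`load_parameters(path)`) to run the model on modified inputs.

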