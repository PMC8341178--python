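# Methods

## Model structure

The comparison of lusutrombopag (LUSU) against prophylactic platelet
transfusion (PT) is a two-phase cohort model evaluated in expectation
(no microsimulation).

**Decision tree (35 days).** The pathway skeleton per arm is
prior-transfusion status × procedure delay × bleeding × rescue; adverse
events and deaths are expanded analytically within each pathway, and a
full leaf-by-leaf enumeration is kept as a test oracle (agreement to
1e-10). Conventions, chosen where the published description is silent:

- *Delayed patients are rescheduled*: they still receive the procedure,
  its cost and its bleeding risk, plus 4 extra hospital days. There is a
  delay cost but no separate terminal branch, and bleeding is defined
  after "planned or rescheduled" procedures.
- *Bleeding risk is independent of delay status* (one probability per
  arm); *rescue* depends on arm and prior-transfusion status and lasts
  exactly one transfusion day.
- *Allergic-reaction risk is linear in transfusion-exposure days*
  (prior-transfusion days, plus one day if rescued), using the unrounded
  0.0004 × 1.17 = 0.000468/day product, in both arms. Survivors of an
  allergic reaction accrue its treatment cost and 4-week disutility.
- *Bleeding and allergic deaths compete independently* within a pathway;
  thrombosis carries no mortality (none is reported).
- *Within-tree deaths do not truncate within-tree QALYs* (the 35-day
  QALY mass is ~0.077, so the truncation error would be < 1e-4); they do
  remove the patient from the lifetime phase.
- *No discounting inside the tree* (horizon under one year).

**Markov phase (lifetime).** Tree survivors enter an annual-cycle
alive/dead cohort, stratified by Child–Pugh class so that the effective
cohort mortality is the membership-weighted average of the class rates
at every cycle (the surviving cohort drifts toward class A). Printed
annual mortality values are applied directly as annual transition
probabilities. Membership is counted at cycle start, with no half-cycle
correction; cycle t is discounted by (1+r)^-t with the first Markov year
(and the tree) undiscounted. The 50-year horizon is 50 cycles. No costs
accrue after the tree: the published cost structure attaches every cost
to the procedure period, and the published lifetime totals equal the
tree totals.

## Key parameters

| parameter | base value | role |
|---|---|---|
| pooled OR, pre-procedure transfusion | 0.04 (95% CI 0.02–0.11) | LUSU-arm transfusion risk via odds transform: 19.35% |
| pooled OR, bleeding | 0.44 (95% CI 0.19–1.02) | LUSU-arm bleeding risk: 18.03% |
| bleeding mortality | 0.83% | largest driver of incremental QALYs |
| transfusion cost/day | 120,206 JPY | see calibration note below |
| transfusion days | LUSU 1.23 / PT 1.17 | per patient transfused |
| baseline utility | 0.808 | CLD health state, both phases |
| discount rate | 2%/yr | costs and QALYs |
| willingness-to-pay | 5,000,000 JPY/QALY | NMB threshold |

All inputs, their one-way ranges and their PSA distribution assignments
are in `src/lusucea/data/base_case.yaml`.

## Calibration of under-specified inputs

Two published inputs are internally inconsistent at their printed
precision; in both cases the package follows the value the published
*results* imply, and documents the choice here.

**Per-day transfusion cost.** The printed components (8,169 JPY/unit ×
12.8 units/day + 15,380 JPY fee = 119,943 JPY) disagree with the
published per-day transfusion cost of 120,206 JPY, and the published
scenario-A cost deltas (20,423 and 5,372 JPY per arm for removing 0.17
and 0.044 expected transfusion days) imply a per-day cost of
~120,100–120,700 JPY. The shipped configuration therefore stores
units/day at the precision implied by the per-day total (12.83217, of
which 12.8 is the rounded display), so the same 120,206 JPY/day prices
both prior and rescue transfusion. With the rounded components instead,
the base-case incremental cost is −1,978 JPY rather than −2,223 JPY
(published: −2,689 JPY).

**Utility age adjustment.** The published general-population regression
(0.9978786 + 0.0218333·male% − 0.002153·age) is implemented exactly
(`general_population_utility`, `cld_utility_at_age`), and
`settings.age_adjust_utility` applies it multiplicatively each cycle.
The flag defaults to **off**: applied at annual cycles with male share
0.62 the adjustment yields 5.98 discounted QALYs per survivor, whereas
the published lifetime totals imply 6.11 — above even the
constant-utility value of 6.08 — so the published model's adjustment
cannot have materially reduced utilities (its male-share scale and
ceiling conventions are not reported). Holding the baseline utility
constant reproduces the published totals to within 0.04 QALYs; the
adjustment remains available for exploration. The male fraction (not
published; default 0.62, typical of the underlying trial populations)
enters only through this optional adjustment and largely cancels in
increments.

Residual, accepted discrepancies: per-arm lifetime costs sit ~0.1% below
the published figures and the incremental cost at −2,223 vs −2,689 JPY —
a constant ~470 JPY offset across all scenarios, consistent with the
published model carrying more internal precision in its meta-analytic
probabilities than the four significant figures printed.

## Sensitivity analyses

**One-way.** Every parameter with a published range is varied alone;
ranges are consumed as printed (95% CIs for the two odds ratios,
thrombosis incidence and bleeding mortality; otherwise the 2.5/97.5
band implied by a 20%-of-mean SE, which is what the printed "±20%"
bounds actually are — except the 15 procedure-mix costs, which are
literal ±20% and cancel between arms). Odds ratios are varied on the OR
scale with the downstream arm probabilities re-derived. Parameters
printed without a range (structural shares, mortality by class, drug
price) are held fixed.

**Probabilistic.** 1000 iterations; every ranged parameter is drawn
independently — lognormal for odds ratios (μ = ln OR, σ from the Wald CI
on the log scale), beta by method of moments for probabilities and
utility quantities (decrements sampled on the magnitude scale), normal
truncated at zero by resampling for costs, units and transfusion days.
SEs come from the 95% CI width where one is published, else 20% of the
mean. Per draw, the LUSU-arm probabilities are re-derived from the
sampled OR and sampled reference rate; no correlation between parameters
is imposed. The analysis is bitwise reproducible for a fixed (seed,
n_iter): one seeded generator, parameters sampled in sorted-id order.
At n = 1000 the binomial standard error of the headline probabilities is
~1.6 percentage points.

**Meta-analysis.** DerSimonian–Laird on the log-OR scale, Wald 95% CI
with z = 1.96, no small-k adjustment; Haldane–Anscombe 0.5-correction
only when a study has an empty cell. The published pooled ORs are
consumed as inputs (the per-trial counts behind them are not published);
the estimator is validated against statsmodels and, on synthetic trial
pairs, for parameter recovery and CI coverage.

## Synthetic data

`synthetic.generate_trial` emulates the structure of the underlying
placebo-controlled trials: two arms of ~100–200 patients, a binary
endpoint at a stated control-arm risk, the treatment arm at the risk
implied by a true odds ratio, events binomial. It reproduces the
marginal event-rate structure only — no covariates, dropout, blocking
or time-to-event structure — so tests built on it validate the
meta-analytic machinery (recovery, coverage, determinism), not the
clinical realism of the trials. `generate_parameter_perturbation`
jitters a parameter set within each quantity's support (logit scale for
probabilities, multiplicative for costs) for property tests of the
engines.

## Numerical choices and degenerate inputs

- Currency is kept as floating-point JPY throughout; rounding only at
  display time.
- The odds transform rejects reference rates of exactly 0 or 1
  (degenerate odds); beta fitting rejects SE² ≥ m(1−m), naming the
  parameter; the zero-SE limit of any family is a point mass.
- A horizon shorter than one year skips the Markov phase entirely
  (scenario C); `run_markov` itself rejects sub-cycle horizons.
- Procedure-mix shares are renormalised (the printed column sums to
  100.1%); the weighted cost is invariant to rescaling all shares.
- The rescue adverse-event component (59 JPY) is stored as printed, not
  recomputed from its footnote (which yields 60.4 JPY).
- ICER is reported only when both increments are positive; all other
  sign combinations carry dominance-style labels.

## Limitations

- The model inherits the published structure: no transitions between
  Child–Pugh classes, no background general-population mortality on top
  of the disease-specific rates, no costs after the procedure period, no
  transfusion-transmitted infections, and exactly two comparators.
- Conventions the publication leaves open (cycle timing, the utility
  age adjustment, per-day cost precision) were fixed as described above;
  alternatives move lifetime QALYs by up to ~0.3 and the incremental
  cost by a few hundred JPY.
- PSA distribution assignments for "normal or partially beta" inputs
  were resolved as truncated normal for all costs and units; a beta
  choice would require support bounds the publication does not give.
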