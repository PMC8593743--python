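# Methods

## The decision problem

Eight outpatient biologics are subsidised for severe chronic plaque
psoriasis in Australia (PBS): adalimumab, etanercept, ustekinumab,
secukinumab, ixekizumab, guselkumab, risankizumab and tildrakizumab.  PBS
rules impose a common treatment rhythm: a 12-week induction period, then
24-week maintenance periods, each ending in a dermatologist review of
PASI75 (≥75% improvement in the Psoriasis Area and Severity Index).
Patients failing a review switch drug; after three failed biologic lines
they move to best supportive care (BSC: cyclosporine plus
calcipotriol/betamethasone foam), assumed to have no further chance of
PASI75.  The model compares *pathways* — each drug as first line, followed
by the two most effective induction agents (risankizumab, then
ixekizumab; guselkumab as third line for cohorts already starting on one
of those) — on total 2020 AUD cost and QALYs over 96 weeks from the
health-system perspective.

## Model structure

A Markov cohort model with 12-week cycles, 8 cycles (96 weeks), no
discounting (configurable `annual_discount_rate`, default 0) and no
mortality.  States: per-line induction (one cycle), per-line maintenance
(tracked by 24-week period position), and absorbing BSC.  Induction
response probabilities come from network meta-analytic 12–16-week PASI75
rates; each 24-week maintenance review reuses one long-term (44–60-week)
PASI75 retention probability per drug, as longer-term data are lacking.

Transitions occur at review boundaries, **including a review that falls
exactly at week 96**: the terminal transition is evaluated and the final
half-cycle reflects the post-review state.  This matters numerically: the
published unrounded ICURs are only reproducible (QALY deltas to 1e-6) when
the terminal review is evaluated, which is also how a cycle-tree
implementation naturally behaves.

## Reward conventions

`RewardConvention(utility_timing, failure_dosing)` controls accrual:

- `half_cycle_on_failure` (default, calibrated): each cycle's utility is
  the mean of its start- and end-boundary state membership (trapezoid) —
  equivalently, patients change state halfway through a cycle, which
  implements the assumption that failures occur mid-cycle.  Per-cycle cost
  rates receive the same correction, with a post-terminal continuation
  rate supplying the trailing half-cycle.
- `cycle_start_membership` / `cycle_end_membership`: plain per-cycle
  accrual with the state at the cycle's start (resp. end); provided to
  expose how sensitive results are to this modelling choice.
- `failure_dosing`: `full_period` (default) charges failures every
  dispense scheduled up to the failed review; `stop_mid_cycle` removes
  dispenses scheduled in the six weeks before it.

Utilities: uncontrolled psoriasis (PASI 16.5, below PASI75) 0.64/year,
controlled (PASI 4.1) 0.89/year, from a UK time-trade-off valuation; BSC
occupants accrue the uncontrolled utility.  QALYs per cycle are
`u × 12/52`.

## Costs

All costs are 2020 AUD to the health system, drug prices net of the
AUD41.00 patient co-payment.  Drug acquisition accrues per *dispense*
(pharmacy supply event), not per injection: the listed prices are pack
prices (adalimumab 2×40 mg and etanercept 4×50 mg ≈ four weeks of supply;
ixekizumab single pens fortnightly during induction, then one 3-pen pack
per 12 weeks; secukinumab 2×150 mg pens = one 300 mg dose; the q8w/q12w
antibodies one dose per pack).  Each drug therefore carries a dose
calendar (clinical schedule) and a dispense calendar (supply schedule);
costs use the latter, with half-open interval counting so boundary
dispenses are never double-charged.

Monitoring: the pre-biologic workup (dermatologist visit AUD113 +
investigations AUD738) is charged once, at the start of the first line —
screening investigations are not repeated at each switch.  Maintenance
monitoring (visit AUD75 + investigations AUD80 per 24 weeks) accrues at
AUD77.5 per maintenance cycle.  BSC costs AUD2,488 in its entry cycle
(12-week cyclosporine induction + foam) and AUD2,950 per cycle thereafter
(half of the 24-week maintenance figures), plus maintenance-rate
monitoring.  Ustekinumab uses the single 45 mg price (85 kg reference
patient).

## Calibration of the convention, and reproduction accuracy

The published within-cycle correction under-determines reward timing, so
the convention was calibrated against the published base case and then
frozen.  Under the defaults above the engine reproduces: all eight arm
QALYs to ≤0.0004 and all QALY *differences* versus tildrakizumab to 1e-6;
seven of eight arm costs to 0.02–1.9%; the frontier and all dominance
labels exactly; the secukinumab ICUR to ~2%.

Two residuals resisted every self-consistent accrual rule we searched and
are reported, not patched: (i) the published ixekizumab-first arm cost is
~10% above what any uniform convention yields, consistent with its
front-loaded induction cost having escaped the half-cycle correction in
the source implementation only for that arm; (ii) the
risankizumab-vs-tildrakizumab cost difference is ~+4% high, which
propagates to that ICUR and to the upper end of its one-way sensitivity
range.  The acceptance tests assert the stated 2% tolerances and the
affected assertions fail honestly.

## Sensitivity analyses

**One-way:** each PASI75 probability moves to its 95% CI bounds; utilities
and the four BSC cost components move ±20%.  The +20% controlled-utility
bound (0.89 × 1.2 = 1.068) is deliberately *not* truncated at 1.0: it is a
symmetric perturbation lever rather than a realisable health state, and
truncation would shrink the reported ICUR ranges asymmetrically (the
published ranges are arithmetically consistent with the unclamped value).
A `clamp_utilities` flag restores truncation.  All arms (reference
included) are re-evaluated at each setting.

**Probabilistic:** 10,000 joint independent draws — Beta for each
efficacy (method of moments; SE = CI width / 3.92), Beta for each utility,
Gamma for each BSC cost component (shape = 1/cv², scale = mean·cv², cv
0.2 by default since no spread is published).  The utility SDs printed in
the source (0.49 and 0.11) describe respondent heterogeneity in the
valuation study and are Beta-infeasible for the uncontrolled state;
since the model consumes *mean* utilities, the PSA propagates the
standard error of the mean (SD/√n, n = 200 respondents by default,
`utility_se_n=None` to sample raw SDs clamped to feasibility).  This
choice is consequential: sampling raw SDs roughly doubles the spread of
QALY differences and cuts the reference arm's acceptability at
AUD50,000/QALY from ~89% to ~72%.  Probabilistic ICURs are ratios of
iteration-averaged increments (means first, ratio second); the CEAC
reports argmax net-monetary-benefit frequencies over a WTP grid of 0 to
100,000 in steps of 1,000 (configurable).

## Verification

Two independent evaluation routes — cycle-by-cycle cohort propagation and
exhaustive enumeration of review-outcome pathways — are required to agree
to 1e-6 AUD / 1e-9 QALYs on the base case and on randomly generated
scenarios (the synthetic generator draws structurally valid scenarios:
coherent CIs, ordered utilities, positive costs, schedule patterns
spanning weekly to q12w supply).  Degenerate scenarios give closed-form
checks: equal utilities ⇒ every arm earns exactly 96/52 × u QALYs; zero
efficacy ⇒ the cohort is entirely in BSC from week 36 and a one-line
strategy buys exactly its induction dispenses; perfect efficacy ⇒ the
cohort never leaves first-line maintenance.  Cohort mass is conserved to
1e-9 every cycle, and dose/dispense counting satisfies partition
additivity by property test.

## What the synthetic generator does and does not emulate

It generates model *inputs* (drug economics and response probabilities),
not patient-level data — there is none in this design.  Passing property
tests therefore demonstrates the arithmetic and invariants of the engine
across the input space, not the external validity of any scenario: real
drug survival (discontinuation for reasons other than measured efficacy
loss), adverse-event costs, weight-based dosing and patient heterogeneity
are all outside the model, as in the source analysis.

## Numerical choices and limitations

Problem sizes are the study's own: 8 cycles, 8 arms, 44 one-way
parameter settings, 10,000 PSA iterations (a fraction of a second in the
vectorised engine; results are bit-reproducible for a fixed seed).
Probabilities in synthetic/degenerate scenarios are kept strictly inside
(0, 1) (degenerate cases use 1e-12 offsets) because exact 0/1 violate the
scenario invariants.  Ties in the CEAC argmax resolve to the first arm in
strategy order; exact cost/QALY ties on the frontier are kept with
deterministic name ordering.  The 96-week horizon cannot speak to lifetime
cost-effectiveness, drug survival, or settings outside the Australian
pricing system.
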