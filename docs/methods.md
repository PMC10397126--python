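# Methods

`lipidcea` implements a three-state Markov cohort model for the
cost-effectiveness of adding a lipid-lowering drug (icosapent ethyl,
evolocumab, alirocumab, ezetimibe, or fenofibrate) to statin therapy,
versus statin monotherapy, in primary and secondary cardiovascular
prevention from the perspective of the German statutory health system.

## Model structure

Health states: *alive without CVD*, *alive with CVD*, *dead*.  Cycles are
one year; the base-case horizon is 20 years with the cohort entering at
age 63 (primary prevention starts everyone in the without-CVD state,
secondary prevention in the with-CVD state).  Six event types are
modelled: non-fatal MI, non-fatal stroke, hospitalization for unstable
angina, coronary revascularization, CVD death, and non-CVD death.
Non-fatal MI and stroke move without-CVD patients into the CVD state and
are counted as recurrent events (cost and disutility, no state change) for
patients already there.  Angina hospitalizations and revascularizations
never change state.  Death is absorbing.

Within a cycle, competing risks are resolved deaths-first: the two death
probabilities act on the cycle-start occupancy and the non-fatal
transitions act on the survivors.  Extreme inputs could make a
probability row sum past one; such rows are proportionally renormalized
with a warning naming the cycle (this never triggers for the shipped
inputs, only for deliberately extreme stress profiles).

## Transition probabilities

Statin-arm annual probabilities per state and event are inputs (see *Input
provenance* below).  All derived quantities are computed on the rate scale,
`r = -ln(1 - p)`:

* **Annualization.** Trial proportions over median follow-up `T` become
  annual probabilities via `1 - (1 - p)^(1/T)` (implemented with
  `log1p`/`expm1`, so annualize-then-compound round-trips to ~1e-16).
* **Prevalence split.** For trials enrolling a mixed population (fraction
  π with established CVD, events `rr` times as likely in that subgroup),
  the whole-trial probability is split by solving
  `π·p_sec + (1-π)·p_prim = p_all`, `p_sec = rr·p_prim`.  Infeasible
  inputs raise rather than clamp.
* **Hazard ratios.** Treatment-arm probabilities are
  `1 - (1 - p)^HR` (a probability-multiplication toggle exists for
  convention matching).  `HR = 1` short-circuits to the identical float so
  a null treatment reproduces the statin arm bit for bit.
* **Risk escalation.** Cardiovascular event rates grow 14%/year and
  non-CVD mortality 10%/year: the rate is multiplied by
  `growth^(t-1)` for cycle `t`, so cycle 1 is unescalated and escalated
  probabilities stay below 1 at any horizon.  The escalation clock is
  cycles since model start, not patient age.  Hazard ratios are applied
  before escalation (the two commute on the rate scale; the order is fixed
  for determinism).

Patients who acquire CVD in the primary-prevention model are thereafter
governed by the with-CVD risks and by the drug's secondary-prevention
hazard ratios, for both arms — the only evidence available for that state.

## Utilities and costs

State utilities come in two age bands (0.65 without / 0.57 with CVD below
age 70; 0.63 / 0.55 at 70+; death 0).  The cohort enters at 63, so ages
below 70 use the 65–70 band.  Acute events subtract a one-cycle decrement
(MI 0.04, stroke 0.12, angina 0.09, revascularization 0.01), applied to
the expected event count.

Costs (2021 euros): annual state costs (€4,522 without CVD; €8,008 with
CVD — the shipped file follows the input table where the source text also
prints €8,088; the value is editable), one-off event costs, cause-specific
one-off death costs (stored as final hospital/home-weighted values, 71%/29%),
and annual therapy prices (statin €131.62 in both arms; the add-on price in
the combination arm only: icosapent ethyl €2,400, evolocumab €5,879.54,
alirocumab €7,508.88, ezetimibe €156.48, fibrate €130.44).  Therapy costs
accrue on alive occupancy at cycle start (no discontinuation); state costs
and utilities use end-of-cycle occupancy.

Discounting: 3%/year for both costs and utilities, cycle `t` weighted by
`(1+r)^-(t-1)` (first year undiscounted); the convention is a flag, since
published models differ.  No half-cycle correction by default (a
trapezoid-style option exists).

## Outcomes

Incremental discounted costs, QALYs, and LYs give ICERs as signed ratios
of unrounded increments; dominant (cheaper, more effective) and dominated
strategies are labelled but the signed ICER is still printed.  NNT is
defined here as 1 over the difference in cumulative undiscounted expected
events per person over the horizon — the reference analyses in this
literature rarely define their NNT, and values printed there are often not
recoverable from any cohort model of this structure, so NNT agreement is
treated as a diagnostic, not a validation gate.  The efficiency frontier
flags simply and extendedly dominated strategies against the statin
origin; a brute-force pairwise/blend oracle checks it in the tests.

## Uncertainty analyses

* **One-way (tornado):** each parameter in turn at its bounds (95% CIs
  for hazard ratios and utilities; ±25% for costs, escalation increments,
  and baseline death probabilities; 0–0.10 for the discount rate), full
  model re-run, sorted by ICER spread.
* **Probabilistic:** 1,000 joint draws by default.  Families follow the
  input table: normal for hazard ratios (sampled on the natural scale,
  truncated at 1e-6, because that is what the table declares; a log-scale
  toggle is provided since log-normal is the field convention), beta for
  utilities and baseline probabilities, gamma for decrements and costs
  (method-of-moments from mean and CI, with ±25% bands read as 95%
  intervals, SE = 0.25·mean/1.96), degenerate for prices, discount rate,
  and escalation.  Parameters are sampled independently; a drawn with-CVD
  utility is capped at the without-CVD draw to preserve state ordering.
  The summary "mean ICER" is the arithmetic mean of per-draw ICERs (the
  ratio-of-means alternative is also reported).  Draw *i* uses an rng
  seeded with `(seed, i)`, so results are independent of the iteration
  count and bit-reproducible.
* **CEAC:** probability of positive net monetary benefit `λ·ΔQ − ΔC`
  per willingness-to-pay grid point (default €0–200,000 in €1,000 steps),
  pairwise against statin; the reported threshold is the first grid value
  with ≥95% acceptability.
* **Scenarios:** drug price ±50%, discounting 0 and 10%, treatment from
  age 55 over 25 years, CVD escalation ±25% of the annual increase.
* **Pricing:** incremental cost is exactly linear in the annual add-on
  price (price × discounted alive-at-cycle-start person-years), so
  threshold prices solve in closed form and are verified by re-running the
  model (tolerance 0.1 €/QALY).

## Input provenance and the synthetic baseline

Hazard ratios, utilities, costs, and run settings are transcribed into
`src/lipidcea/data/table1.yaml`.  The statin-arm baseline transition
probabilities (and per-event fibrate hazard ratios) were published only in
supplementary material that is not redistributable here;
`baseline_probabilities_synthetic.yaml` is an explicitly labelled
synthetic stand-in whose magnitudes emulate the control-arm event rates of
large outcome trials in statin-treated populations (annualized over median
follow-up; split at the stated CVD prevalence with a relative risk of 2).
All structural results (orderings, conservation laws, oracle agreement)
are independent of this choice; absolute ICERs are not, so outputs from
the shipped file characterize the method on realistic inputs rather than
reproducing any specific published table.  Replacing the baseline file
with transcribed values is the supported route to such a reproduction.

## Synthetic trial generator

`synthetic.SyntheticTruth` defines a trial world by annual without-CVD
event probabilities, a CVD prevalence, a CVD-vs-non-CVD relative risk,
per-event hazard ratios, arm size, and follow-up.  `simulate_trial` draws
per-arm binomial counts at the compounded mixed-population probability and
subgroup composite outcomes; `recover_probabilities` runs the derivation
chain back.  Defaults (n = 100,000/arm, follow-up 4.9 years, prevalence
0.6–0.71, rr = 2) match the scale of the trials this literature draws on.
The generator emulates arm-level summaries only: no censoring, no
within-patient correlation between event types, no calendar-time trends —
so passing recovery tests validates the derivation algebra, not the
handling of real trial reporting quirks.

## Numerical and testing choices

Probability arithmetic uses `log1p`/`expm1` throughout; occupancy
conservation is asserted at 1e-12 per cycle.  The cohort engine is checked
against a 100,000-individual microsimulation replaying the identical
per-cycle probabilities and competing-risk order (agreement within 3
Monte-Carlo SEs).  The full two-arm 20-year run takes ~20 ms and a
1,000-draw PSA well under a minute on one CPU, so tests and the
reproduction script run at full problem size except where noted.

## Known limitations

Treatment side effects, discontinuation, background life-table mortality
(beyond the trial-derived, escalated death risks), triple/quadruple
combinations, and transfer to non-German settings are out of scope.
Cross-trial comparisons inherit the trials' differing populations and
eras.  Negative ICERs are reported signed; interpret them only together
with the dominance label.
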