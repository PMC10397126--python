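# lipidcea

Cost-effectiveness modelling of add-on lipid-lowering therapy for
cardiovascular prevention, from the perspective of the German statutory
health system.  The package compares statin monotherapy against statin
plus one of five add-on drugs — icosapent ethyl, evolocumab, alirocumab,
ezetimibe, or fenofibrate — in primary prevention (patients without
established cardiovascular disease) and secondary prevention (patients
with it).  It is aimed at health-economics researchers and HTA analysts
who need a transparent, fully tested re-implementation of this class of
decision model rather than a spreadsheet.

## The model

A deterministic Markov cohort model with three health states — *alive
without CVD*, *alive with CVD*, *dead* — over annual cycles (default
20 years, cohort entry at age 63).  Six event types drive costs,
quality-of-life decrements, and state changes: non-fatal MI, non-fatal
stroke, unstable-angina hospitalization, coronary revascularization, CVD
death, and non-CVD death.  Statin-arm annual event probabilities
\(p\) are inputs; the combination arm applies each drug's trial hazard
ratio on the rate scale, \(p_{tx} = 1-(1-p)^{HR}\); cardiovascular and
non-cardiovascular risks escalate by 14%/year and 10%/year on the rate
scale.  Outcomes are discounted (3%/year) incremental costs ΔC, QALYs ΔQ
and life years ΔLY, with

&nbsp;&nbsp;&nbsp;&nbsp;ICER = ΔC / ΔQ &nbsp;(€/QALY),

numbers needed to treat per event type, an efficiency frontier with
extended dominance, one-way (tornado) and probabilistic sensitivity
analyses, cost-effectiveness acceptability curves based on net monetary
benefit λ·ΔQ − ΔC, and closed-form price-threshold analysis.
`docs/methods.md` documents every modelling convention and numerical
choice.

**Inputs.** Published hazard ratios, utilities, costs and settings ship in
`src/lipidcea/data/table1.yaml`.  The statin-arm baseline transition
probabilities are *synthetic stand-ins of realistic magnitude*
(`baseline_probabilities_synthetic.yaml`, labelled as such): the original
values appeared only in non-redistributable supplementary material.
Structural conclusions (orderings, dominance, conservation properties) do
not depend on them; absolute ICERs do.  Point either file path at your own
transcriptions to analyze different inputs.

## Worked example

```python
import lipidcea as L

params = L.load_parameters(drug="icosapent_ethyl", setting="secondary")
result = L.compare_arms(params)
print(f"dQALY={result.delta_qaly:.3f}  dCost=EUR {result.delta_cost:,.0f}  "
      f"ICER={result.icer_per_qaly:,.0f} EUR/QALY ({result.dominance})")
print(f"NNT non-fatal MI: {result.nnt['nonfatal_mi']:.1f}")
```

prints

```
dQALY=0.309  dCost=EUR 26,516  ICER=85,944 EUR/QALY (tradeoff)
NNT non-fatal MI: 4.7
```

Over 20 years, adding icosapent ethyl to statin for a secondary-prevention
cohort (on the shipped synthetic baselines) gains 0.309 QALYs per person
at an extra cost of €26,516, i.e. €85,944 per QALY gained — a genuine
trade-off (more effect at more cost), with one non-fatal MI averted per
4.7 patients treated.

The same analyses are scripted end to end in `analysis/`
(`01_base_case.py` … `05_synthetic_recovery.py`), each writing its tables
under `results/`, and exposed on the command line:

```sh
lipidcea basecase --drug icosapent_ethyl --setting secondary --out run/
lipidcea psa --drug ezetimibe --setting secondary --iterations 1000 --seed 42 --out run/
lipidcea frontier --setting secondary --out run/
```

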