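#!/usr/bin/env python
"""Scenario and drug-pricing analyses.

Re-runs the model under the shipped scenario set (drug price ±50%,
discounting at 0 and 10%, treatment from age 55 over 25 years, CVD risk
escalation at ±25% of the annual increase) for every comparison, and
computes the annual PCSK9-inhibitor prices needed to match icosapent
ethyl's secondary-prevention ICER.
"""

import json
from pathlib import Path

from lipidcea import (
    available_comparisons,
    compare_arms,
    load_parameters,
    price_threshold,
    scenario_analysis,
    shipped_scenarios,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

scenarios = {}
for drug, setting in available_comparisons():
    params = load_parameters(drug=drug, setting=setting)
    block = {"base_case": compare_arms(params).icer_per_qaly}
    for name, ov in shipped_scenarios().items():
        block[name] = scenario_analysis(params, ov).icer_per_qaly
    scenarios[f"{drug}_{setting}"] = block
(RESULTS / "scenarios.json").write_text(json.dumps(scenarios, indent=2) + "\n")

print("scenario ICERs (EUR/QALY):")
for tag, block in scenarios.items():
    print(f"\n{tag}")
    for name, icer in block.items():
        print(f"  {name:>28}: {'undefined' if icer is None else format(icer, ',.0f')}")

target = compare_arms(
    load_parameters(drug="icosapent_ethyl", setting="secondary")).icer_per_qaly
pricing = {}
for drug in ("evolocumab", "alirocumab"):
    params = load_parameters(drug=drug, setting="secondary")
    res = price_threshold(params, target)
    pricing[drug] = {
        "target_icer": target,
        "list_price": res.base_price,
        "threshold_price": res.annual_price,
        "required_cut_pct": (None if res.annual_price is None
                             else 100 * (1 - res.annual_price / res.base_price)),
    }
    if res.annual_price is None:
        print(f"\n{drug}: no annual price reaches ICER {target:,.0f} EUR/QALY")
    else:
        print(f"\n{drug}: ICER {target:,.0f} EUR/QALY needs annual price "
              f"EUR {res.annual_price:,.2f} "
              f"({pricing[drug]['required_cut_pct']:.0f}% below list)")
(RESULTS / "price_thresholds.json").write_text(json.dumps(pricing, indent=2) + "\n")
print(f"\nwritten: {RESULTS / 'scenarios.json'}, {RESULTS / 'price_thresholds.json'}")
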