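#!/usr/bin/env python
"""One-way (tornado) sensitivity of the ICER to each input parameter.

For icosapent ethyl (both settings): every hazard ratio at its 95% CI ends,
utilities and decrements at their CI ends, costs at ±25%, the discount rate
over 0–0.10, risk escalation at ±25% of the annual increase, and baseline
death probabilities at ±25%.  Writes one tornado CSV per setting.
"""

from pathlib import Path

import pandas as pd

from lipidcea import load_parameters, one_way_sensitivity

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

for setting in ("primary", "secondary"):
    params = load_parameters(drug="icosapent_ethyl", setting=setting)
    entries = one_way_sensitivity(params)
    df = pd.DataFrame([e.__dict__ for e in entries])
    out = RESULTS / f"tornado_icosapent_{setting}.csv"
    df.to_csv(out, index=False)
    finite = df[df["spread"].apply(lambda s: s == s and s != float("inf"))]
    print(f"\n{setting} prevention — five widest ICER swings:")
    print(finite.head(5)[["parameter", "icer_at_low", "icer_at_high", "spread"]]
          .round(0).to_string(index=False))
    print(f"written: {out}")
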