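"""Deterministic Markov cohort simulation.

Three health states — alive without CVD, alive with CVD, dead — tracked as
occupancy fractions over annual cycles.  Non-fatal MI and stroke move
patients without CVD into the CVD state (and are counted as recurrent
events, without a state change, for patients already in it); hospitalization
for unstable angina and coronary revascularization are tallied among the
alive without altering state; cardiovascular and non-cardiovascular death
absorb into the dead state.

Within a cycle, competing risks are resolved deaths-first: the two death
probabilities act on the state occupancy, and non-fatal transitions act on
the survivors.  If a probability row sums past 1 it is proportionally
renormalized and a warning is issued naming the cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epi import build_cycle_probabilities
from .parameters import (
    ARM_COMBINATION,
    EVENTS,
    NONFATAL_EVENTS,
    CostParams,
    ModelSettings,
    ParameterSet,
    UtilityParams,
)


class ModelWarning(UserWarning):
    """Raised when a probability row needs renormalization."""


@dataclass
class CohortTrace:
    """Per-cycle results of one cohort run.

    ``cycles`` has one row per cycle with occupancy after transition,
    expected per-person event counts, and (un)discounted LY, QALY, and cost;
    ``totals`` aggregates them over the horizon.
    """

    arm: str
    setting: str
    drug: str
    cycles: pd.DataFrame
    totals: dict[str, float] = field(default_factory=dict)

    def cumulative_events(self, event: str, discounted: bool = False) -> float:
        col = f"ev_{event}"
        if col not in self.cycles.columns:
            raise KeyError(f"unknown event type {event!r}")
        if discounted:
            return float((self.cycles[col] * self.cycles["discount"]).sum())
        return float(self.cycles[col].sum())

    def to_csv(self, path) -> None:
        self.cycles.to_csv(path, index=False)


def _renormalize(probs: dict[str, float], cycle: int, label: str) -> dict[str, float]:
    total = sum(probs.values())
    if total > 1.0:
        warnings.warn(
            f"cycle {cycle}: {label} exit probabilities sum to {total:.4f} > 1; "
            f"renormalizing proportionally",
            ModelWarning,
            stacklevel=3,
        )
        probs = {k: v / total for k, v in probs.items()}
    return probs


def run_cohort(
    params: ParameterSet,
    arm: str,
    setting: str | None = None,
    probability_table: pd.DataFrame | None = None,
) -> CohortTrace:
    """Simulate one arm of the cohort over the model horizon.

    Primary-prevention cohorts start fully in "alive without CVD";
    secondary-prevention cohorts in "alive with CVD".  ``probability_table``
    may inject a pre-built per-cycle table (used by tests); otherwise it is
    derived from ``params``.
    """
    setting = setting or params.setting
    s = params.settings
    horizon = s.time_horizon
    if probability_table is None:
        probability_table = build_cycle_probabilities(params, arm, setting, horizon)

    occ_wo, occ_wc, occ_dead = (1.0, 0.0, 0.0) if setting == "primary" else (0.0, 1.0, 0.0)

    rows = []
    for t in range(1, horizon + 1):
        p = probability_table.loc[t]
        alive_start = occ_wo + occ_wc
        events = {ev: 0.0 for ev in EVENTS}

        # --- alive without CVD: deaths first, then MI/stroke move survivors
        d = _renormalize(
            {ev: p[("alive_without_cvd", ev)] for ev in ("cvd_death", "noncvd_death")},
            t, "without-CVD death")
        events["cvd_death"] += occ_wo * d["cvd_death"]
        events["noncvd_death"] += occ_wo * d["noncvd_death"]
        surv_wo = occ_wo * (1.0 - d["cvd_death"] - d["noncvd_death"])
        m = _renormalize(
            {ev: p[("alive_without_cvd", ev)] for ev in ("nonfatal_mi", "nonfatal_stroke")},
            t, "without-CVD non-fatal transition")
        events["nonfatal_mi"] += surv_wo * m["nonfatal_mi"]
        events["nonfatal_stroke"] += surv_wo * m["nonfatal_stroke"]
        movers = surv_wo * (m["nonfatal_mi"] + m["nonfatal_stroke"])
        events["unstable_angina_hosp"] += surv_wo * p[("alive_without_cvd", "unstable_angina_hosp")]
        events["coronary_revasc"] += surv_wo * p[("alive_without_cvd", "coronary_revasc")]

        # --- alive with CVD: deaths first, recurrent events without state change
        d2 = _renormalize(
            {ev: p[("alive_with_cvd", ev)] for ev in ("cvd_death", "noncvd_death")},
            t, "with-CVD death")
        events["cvd_death"] += occ_wc * d2["cvd_death"]
        events["noncvd_death"] += occ_wc * d2["noncvd_death"]
        surv_wc = occ_wc * (1.0 - d2["cvd_death"] - d2["noncvd_death"])
        for ev in ("nonfatal_mi", "nonfatal_stroke", "unstable_angina_hosp", "coronary_revasc"):
            events[ev] += surv_wc * p[("alive_with_cvd", ev)]

        occ_wo = surv_wo - movers
        occ_wc = surv_wc + movers
        occ_dead = 1.0 - occ_wo - occ_wc

        rows.append({
            "cycle": t,
            "age": s.start_age + (t - 1),
            "alive_start": alive_start,
            "occ_alive_without_cvd": occ_wo,
            "occ_alive_with_cvd": occ_wc,
            "occ_dead": occ_dead,
            **{f"ev_{ev}": events[ev] for ev in EVENTS},
        })

    trace = CohortTrace(arm=arm, setting=setting, drug=params.drug,
                        cycles=pd.DataFrame(rows))
    accumulate_outcomes(trace, params.utilities, params.costs, s, arm=arm)
    return trace


def accumulate_outcomes(
    trace: CohortTrace,
    utilities: UtilityParams,
    costs: CostParams,
    settings: ModelSettings,
    arm: str | None = None,
) -> dict[str, float]:
    """Attach LY, QALY, and cost streams (and totals) to a cohort trace.

    Cycle QALY = occupancy-weighted state utility minus expected event
    counts times their one-cycle decrements.  Cycle cost = annual state
    costs on end-of-cycle alive occupancy, drug and statin prices on alive
    occupancy at cycle start (combination arm pays both, statin arm only the
    statin), one-off event costs on expected counts, and cause-specific
    death costs on the dying fractions.
    """
    arm = arm or trace.arm
    df = trace.cycles
    drug_price = costs.annual_drug_cost if arm == ARM_COMBINATION else 0.0
    therapy_price = drug_price + costs.annual_statin_cost

    ly, qaly, cost, disc = [], [], [], []
    for row in df.itertuples(index=False):
        age = row.age
        occ_wo, occ_wc = row.occ_alive_without_cvd, row.occ_alive_with_cvd
        cyc_ly = occ_wo + occ_wc
        cyc_qaly = (occ_wo * utilities.state_utility("alive_without_cvd", age)
                    + occ_wc * utilities.state_utility("alive_with_cvd", age))
        for ev in NONFATAL_EVENTS:
            cyc_qaly -= getattr(row, f"ev_{ev}") * utilities.decrement(ev)
        cyc_cost = (occ_wo * costs.annual_state["alive_without_cvd"].value
                    + occ_wc * costs.annual_state["alive_with_cvd"].value
                    + row.alive_start * therapy_price)
        for ev in NONFATAL_EVENTS:
            cyc_cost += getattr(row, f"ev_{ev}") * costs.event[ev].value
        cyc_cost += row.ev_cvd_death * costs.death["cvd_death"].value
        cyc_cost += row.ev_noncvd_death * costs.death["noncvd_death"].value

        w = settings.discount_factor(int(row.cycle))
        # optional trapezoid-style correction: half weight on the end cycles
        if settings.half_cycle_correction and int(row.cycle) in (1, settings.time_horizon):
            w *= 0.5
        ly.append(cyc_ly)
        qaly.append(cyc_qaly)
        cost.append(cyc_cost)
        disc.append(w)

    df["ly"], df["qaly"], df["cost"], df["discount"] = ly, qaly, cost, disc
    df["ly_disc"] = df["ly"] * df["discount"]
    df["qaly_disc"] = df["qaly"] * df["discount"]
    df["cost_disc"] = df["cost"] * df["discount"]

    totals = {
        "ly": float(df["ly"].sum()),
        "qaly": float(df["qaly"].sum()),
        "cost": float(df["cost"].sum()),
        "ly_disc": float(df["ly_disc"].sum()),
        "qaly_disc": float(df["qaly_disc"].sum()),
        "cost_disc": float(df["cost_disc"].sum()),
        **{f"ev_{ev}": float(df[f"ev_{ev}"].sum()) for ev in EVENTS},
    }
    trace.totals = totals
    return totals
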