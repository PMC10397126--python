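"""Incremental cost-effectiveness analysis.

Compares the combination arm (statin + add-on drug) against statin
monotherapy: incremental discounted costs, QALYs and LYs, ICERs, numbers
needed to treat, the efficiency frontier across strategies, one-way
(tornado) sensitivity, scenario re-runs, and price-threshold analysis.

ICERs are signed ratios of unrounded increments; negative ICERs are
reported as printed in health-economic tables, with a dominance label
(dominant: cheaper and more effective; dominated: costlier and less
effective) alongside so the sign is never misread.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .engine import CohortTrace, run_cohort
from .parameters import (
    ALIVE_STATES,
    ARM_COMBINATION,
    ARM_STATIN,
    EVENTS,
    Estimate,
    FATAL_EVENTS,
    NONFATAL_EVENTS,
    ParameterSet,
)


@dataclass(frozen=True)
class CEResult:
    """Incremental outcomes of one drug-vs-statin comparison."""

    drug: str
    setting: str
    delta_qaly: float
    delta_ly: float
    delta_cost: float
    icer_per_qaly: float | None   # None when the increment is zero
    icer_per_ly: float | None
    dominance: str                # dominant | dominated | tradeoff
    nnt: dict[str, float | None] = field(default_factory=dict)
    horizon: int = 20
    discount_rate: float = 0.03

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _icer(delta_cost: float, delta_effect: float) -> float | None:
    if delta_effect == 0.0:
        return None
    return delta_cost / delta_effect


def _dominance(delta_cost: float, delta_qaly: float) -> str:
    if delta_cost < 0 and delta_qaly > 0:
        return "dominant"
    if delta_cost > 0 and delta_qaly < 0:
        return "dominated"
    return "tradeoff"


def nnt(trace_treat: CohortTrace, trace_control: CohortTrace, event: str) -> float | None:
    """Number needed to treat to prevent one event over the model horizon.

    Defined as 1 over the difference in cumulative undiscounted expected
    events per person (control minus treatment); None when the treatment
    does not reduce the event.
    """
    if event not in EVENTS:
        raise KeyError(f"unknown event type {event!r}")
    diff = trace_control.cumulative_events(event) - trace_treat.cumulative_events(event)
    if diff <= 0:
        return None
    return 1.0 / diff


def compare_arms(params: ParameterSet) -> CEResult:
    """Run both arms and compute the incremental comparison."""
    control = run_cohort(params, ARM_STATIN)
    treat = run_cohort(params, ARM_COMBINATION)
    return compare_traces(treat, control, params)


def compare_traces(
    treat: CohortTrace, control: CohortTrace, params: ParameterSet
) -> CEResult:
    dq = treat.totals["qaly_disc"] - control.totals["qaly_disc"]
    dly = treat.totals["ly_disc"] - control.totals["ly_disc"]
    dc = treat.totals["cost_disc"] - control.totals["cost_disc"]
    return CEResult(
        drug=params.drug,
        setting=params.setting,
        delta_qaly=dq,
        delta_ly=dly,
        delta_cost=dc,
        icer_per_qaly=_icer(dc, dq),
        icer_per_ly=_icer(dc, dly),
        dominance=_dominance(dc, dq),
        nnt={ev: nnt(treat, control, ev) for ev in EVENTS},
        horizon=params.settings.time_horizon,
        discount_rate=params.settings.discount_rate,
    )


# ---------------------------------------------------------------------------
# Efficiency frontier


@dataclass(frozen=True)
class FrontierPoint:
    label: str
    delta_qaly: float
    delta_cost: float
    on_frontier: bool
    status: str  # frontier | dominated | extended_dominated


def efficiency_frontier(results: list[CEResult]) -> list[FrontierPoint]:
    """Efficiency frontier over strategies, anchored at the statin origin.

    A strategy is simply dominated if another point (including the origin)
    offers at least the QALYs at no more cost (one strictly better), and
    extendedly dominated if a blend of two other strategies does.  The
    frontier is the remaining lower-right convex hull, sorted by ΔQALY.
    """
    pts = [("statin", 0.0, 0.0)] + [(r.drug, r.delta_qaly, r.delta_cost) for r in results]
    n = len(pts)
    status = ["frontier"] * n

    for i, (_, qi, ci) in enumerate(pts):
        for j, (_, qj, cj) in enumerate(pts):
            if i == j:
                continue
            if qj >= qi and cj <= ci and (qj > qi or cj < ci):
                status[i] = "dominated"
                break

    # extended dominance: a convex combination of two non-dominated points
    # achieves the same QALYs at lower cost
    changed = True
    while changed:
        changed = False
        live = [k for k in range(n) if status[k] == "frontier"]
        for i in live:
            _, qi, ci = pts[i]
            for a in live:
                for b in live:
                    if i in (a, b) or a == b:
                        continue
                    _, qa, ca = pts[a]
                    _, qb, cb = pts[b]
                    if not (min(qa, qb) <= qi <= max(qa, qb)) or qa == qb:
                        continue
                    w = (qi - qa) / (qb - qa)
                    blend_cost = ca + w * (cb - ca)
                    if blend_cost < ci - 1e-12:
                        status[i] = "extended_dominated"
                        changed = True
                        break
                if status[i] != "frontier":
                    break

    out = [
        FrontierPoint(label, dq, dc, status[k] == "frontier", status[k])
        for k, (label, dq, dc) in enumerate(pts)
    ]
    out.sort(key=lambda p: (p.delta_qaly, p.delta_cost))
    return out


# ---------------------------------------------------------------------------
# One-way (tornado) sensitivity


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float | None
    icer_at_high: float | None
    spread: float


def _set_hr(ps: ParameterSet, setting: str, event: str, value: float) -> ParameterSet:
    ps = ps.deepcopy()
    hrs = dict(ps.hazard_ratios[setting].hazard_ratios)
    old = hrs[event]
    hrs[event] = Estimate(value, min(value, old.low), max(value, old.high))
    object.__setattr__(ps.hazard_ratios[setting], "hazard_ratios", hrs)
    return ps


def _set_estimate(ps: ParameterSet, block: str, key: str, value: float) -> ParameterSet:
    ps = ps.deepcopy()
    if block == "utility_state":
        group, band = key
        target = ps.utilities.without_cvd if group == "without_cvd" else ps.utilities.with_cvd
        new = dict(target)
        new[band] = Estimate(value, min(value, new[band].low), max(value, new[band].high))
        object.__setattr__(
            ps.utilities, "without_cvd" if group == "without_cvd" else "with_cvd", new)
    elif block == "utility_decrement":
        new = dict(ps.utilities.decrements)
        new[key] = Estimate(value, min(value, new[key].low), max(value, new[key].high))
        object.__setattr__(ps.utilities, "decrements", new)
    elif block in ("cost_state", "cost_event", "cost_death"):
        attr = {"cost_state": "annual_state", "cost_event": "event",
                "cost_death": "death"}[block]
        new = dict(getattr(ps.costs, attr))
        new[key] = Estimate(value, min(value, new[key].low), max(value, new[key].high))
        object.__setattr__(ps.costs, attr, new)
    elif block == "baseline":
        state, event = key
        attr = "without_cvd" if state == "alive_without_cvd" else "with_cvd"
        new = dict(getattr(ps.baseline, attr))
        new[event] = value
        object.__setattr__(ps.baseline, attr, new)
    else:
        raise KeyError(block)
    return ps


def default_owsa_bounds(params: ParameterSet) -> list[tuple[str, object]]:
    """The shipped one-way sensitivity parameter list.

    Hazard ratios at their 95% CI ends, state utilities and decrements at
    their CI ends, every cost at ±25%, the discount rate over 0–0.10, the
    annual risk increases at ±25% of the increase, and the baseline death
    probabilities at ±25%.
    """
    entries: list[tuple[str, object]] = []
    for setting, hr_set in params.hazard_ratios.items():
        for event in EVENTS:
            entries.append((f"hr_{setting}_{event}", ("hr", setting, event)))
    for group in ("without_cvd", "with_cvd"):
        for band in ("age_65_70", "age_70_plus"):
            entries.append((f"utility_{group}_{band}", ("utility_state", (group, band))))
    for event in NONFATAL_EVENTS:
        entries.append((f"decrement_{event}", ("utility_decrement", event)))
    for key in ("alive_without_cvd", "alive_with_cvd"):
        entries.append((f"cost_state_{key}", ("cost_state", key)))
    for event in NONFATAL_EVENTS:
        entries.append((f"cost_event_{event}", ("cost_event", event)))
    for event in FATAL_EVENTS:
        entries.append((f"cost_death_{event}", ("cost_death", event)))
    entries.append(("discount_rate", ("setting", "discount_rate")))
    entries.append(("cvd_risk_growth", ("setting", "cvd_risk_growth")))
    entries.append(("noncvd_risk_growth", ("setting", "noncvd_risk_growth")))
    for state in ALIVE_STATES:
        for event in FATAL_EVENTS:
            entries.append((f"baseline_{state}_{event}", ("baseline", (state, event))))
    return entries


def _bounds_for(params: ParameterSet, spec) -> tuple[float, float]:
    kind = spec[0]
    if kind == "hr":
        est = params.hazard_ratios[spec[1]].hazard_ratios[spec[2]]
        return est.low, est.high
    if kind == "utility_state":
        group, band = spec[1]
        block = params.utilities.without_cvd if group == "without_cvd" else params.utilities.with_cvd
        return block[band].low, block[band].high
    if kind == "utility_decrement":
        est = params.utilities.decrements[spec[1]]
        return est.low, est.high
    if kind in ("cost_state", "cost_event", "cost_death"):
        attr = {"cost_state": "annual_state", "cost_event": "event",
                "cost_death": "death"}[kind]
        est = getattr(params.costs, attr)[spec[1]]
        return est.low, est.high
    if kind == "setting":
        if spec[1] == "discount_rate":
            return 0.0, 0.10
        growth = getattr(params.settings, spec[1])
        increase = growth - 1.0
        return 1.0 + 0.75 * increase, 1.0 + 1.25 * increase
    if kind == "baseline":
        state, event = spec[1]
        p = params.baseline.for_state(state)[event]
        return 0.75 * p, min(1.25 * p, 0.999999)
    raise KeyError(spec)


def _apply_bound(params: ParameterSet, spec, value: float) -> ParameterSet:
    kind = spec[0]
    if kind == "hr":
        return _set_hr(params, spec[1], spec[2], value)
    if kind == "setting":
        return params.replace(
            settings=dataclasses.replace(params.settings, **{spec[1]: value}))
    return _set_estimate(params, kind, spec[1], value)


def one_way_sensitivity(
    params: ParameterSet,
    bounds: list[tuple[str, object]] | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis: re-run the full model with one parameter at a time
    set to each of its bounds; entries sorted by ICER spread, descending."""
    specs = bounds if bounds is not None else default_owsa_bounds(params)
    entries = []
    for name, spec in specs:
        lo, hi = _bounds_for(params, spec)
        icer_lo = compare_arms(_apply_bound(params, spec, lo)).icer_per_qaly
        icer_hi = compare_arms(_apply_bound(params, spec, hi)).icer_per_qaly
        spread = (abs(icer_hi - icer_lo)
                  if icer_lo is not None and icer_hi is not None else float("inf"))
        entries.append(TornadoEntry(name, lo, hi, icer_lo, icer_hi, spread))
    entries.sort(key=lambda e: -e.spread)
    return entries


# ---------------------------------------------------------------------------
# Scenario and pricing analyses


@dataclass(frozen=True)
class ScenarioOverrides:
    """Settings overrides for a scenario re-run; None leaves the base value."""

    price_multiplier: float = 1.0
    discount_rate: float | None = None
    time_horizon: int | None = None
    start_age: float | None = None
    cvd_risk_growth: float | None = None
    noncvd_risk_growth: float | None = None


def apply_overrides(params: ParameterSet, ov: ScenarioOverrides) -> ParameterSet:
    ps = params.deepcopy()
    if ov.price_multiplier != 1.0:
        object.__setattr__(ps.costs, "annual_drug_cost",
                           ps.costs.annual_drug_cost * ov.price_multiplier)
    changes = {
        k: getattr(ov, k)
        for k in ("discount_rate", "time_horizon", "start_age",
                  "cvd_risk_growth", "noncvd_risk_growth")
        if getattr(ov, k) is not None
    }
    if changes:
        ps = ps.replace(settings=dataclasses.replace(ps.settings, **changes))
    return ps


def scenario_analysis(
    params: ParameterSet, overrides: ScenarioOverrides | None = None
) -> CEResult:
    """Full model re-run under scenario overrides (no-op overrides reproduce
    the base case exactly)."""
    if overrides is None:
        overrides = ScenarioOverrides()
    return compare_arms(apply_overrides(params, overrides))


def shipped_scenarios() -> dict[str, ScenarioOverrides]:
    """The standard scenario set: drug price ±50%, discount rate 0 and 10%,
    earlier treatment start (age 55, 25-year horizon), and risk escalation
    at ±25% of the annual increase."""
    return {
        "price_minus_50pct": ScenarioOverrides(price_multiplier=0.5),
        "price_plus_50pct": ScenarioOverrides(price_multiplier=1.5),
        "discount_0pct": ScenarioOverrides(discount_rate=0.0),
        "discount_10pct": ScenarioOverrides(discount_rate=0.10),
        "start_55_horizon_25": ScenarioOverrides(start_age=55.0, time_horizon=25),
        "cvd_escalation_minus_25pct": ScenarioOverrides(cvd_risk_growth=1.0 + 0.14 * 0.75),
        "cvd_escalation_plus_25pct": ScenarioOverrides(cvd_risk_growth=1.0 + 0.14 * 1.25),
    }


@dataclass(frozen=True)
class PriceThresholdResult:
    drug: str
    setting: str
    target_icer: float
    annual_price: float | None    # None when no price can reach the target
    base_price: float
    icer_at_price: float | None


def price_threshold(params: ParameterSet, target_icer: float) -> PriceThresholdResult:
    """Annual add-on price at which the ICER equals ``target_icer``.

    The incremental cost is linear in the annual price (therapy cost
    accrues proportionally to alive occupancy), so the threshold solves in
    closed form; the result is verified by re-running the model at the
    returned price (|ICER − target| < 0.1 €/QALY).
    """
    base = compare_arms(params)
    if base.delta_qaly is None or base.delta_qaly <= 0:
        return PriceThresholdResult(params.drug, params.setting, target_icer,
                                    None, params.costs.annual_drug_cost, None)
    treat = run_cohort(params, ARM_COMBINATION)
    # discounted person-years on therapy in the combination arm
    exposure = float((treat.cycles["alive_start"] * treat.cycles["discount"]).sum())
    price0 = params.costs.annual_drug_cost
    price = price0 + (target_icer * base.delta_qaly - base.delta_cost) / exposure

    check_params = params.deepcopy()
    object.__setattr__(check_params.costs, "annual_drug_cost", price)
    achieved = compare_arms(check_params).icer_per_qaly
    if achieved is None or abs(achieved - target_icer) > 0.1:
        raise RuntimeError(
            f"price threshold verification failed: ICER {achieved} at price {price}"
        )
    return PriceThresholdResult(params.drug, params.setting, target_icer,
                                price, price0, achieved)
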