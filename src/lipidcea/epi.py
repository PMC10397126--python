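"""Derivation of per-cycle transition probabilities.

Trial outcomes observed over a median follow-up are annualized under a
constant-hazard assumption, split into distinct risks for patients with and
without established CVD, modified by the treatment-effect hazard ratio for
the combination arm, and escalated cycle by cycle for rising cardiovascular
(14%/year) and non-cardiovascular (10%/year) background risk.

All transformations act on the rate scale: a probability p over one cycle
corresponds to the rate r = -ln(1 - p), which keeps every derived
probability inside [0, 1) regardless of horizon or escalation factor.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .parameters import (
    ALIVE_STATES,
    ARM_COMBINATION,
    ARM_STATIN,
    CVD_EVENTS,
    EVENTS,
    ParameterError,
    ParameterSet,
)


def annualize_probability(p_observed: float, followup_years: float) -> float:
    """Convert an event proportion over a follow-up period to a 1-year
    probability, assuming a constant event rate.

    Returns ``1 - (1 - p)^(1/T)``.  Raises for p = 1 (infinite rate).
    """
    if not (0.0 <= p_observed <= 1.0):
        raise ValueError(f"proportion {p_observed} outside [0, 1]")
    if p_observed == 1.0:
        raise ValueError("proportion of 1 implies an infinite event rate")
    if followup_years <= 0:
        raise ValueError("follow-up must be positive")
    # log-space form: numerically exact inverse of compound_probability
    return -math.expm1(math.log1p(-p_observed) / followup_years)


def compound_probability(p_annual: float, years: float) -> float:
    """Inverse of :func:`annualize_probability`: probability over ``years``."""
    if not (0.0 <= p_annual < 1.0):
        raise ValueError(f"annual probability {p_annual} outside [0, 1)")
    return -math.expm1(math.log1p(-p_annual) * years)


def split_by_prevalence(
    p_all: float, prevalence_cvd: float, rr_cvd_vs_noncvd: float
) -> tuple[float, float]:
    """Split a whole-population event probability into risks for patients
    without CVD (primary prevention) and with CVD (secondary prevention).

    Solves the two-equation system

        prevalence * p_secondary + (1 - prevalence) * p_primary = p_all
        p_secondary = rr * p_primary

    and returns ``(p_primary, p_secondary)``.  Raises if the implied
    secondary risk exceeds 1 (infeasible inputs) — results are never
    clamped.
    """
    if not (0.0 <= p_all <= 1.0):
        raise ValueError(f"p_all {p_all} outside [0, 1]")
    if not (0.0 < prevalence_cvd < 1.0):
        raise ValueError("prevalence must lie strictly between 0 and 1")
    if rr_cvd_vs_noncvd <= 0:
        raise ValueError("relative risk must be positive")
    denom = (1.0 - prevalence_cvd) + prevalence_cvd * rr_cvd_vs_noncvd
    p_primary = p_all / denom
    p_secondary = rr_cvd_vs_noncvd * p_primary
    if p_secondary > 1.0 or p_primary > 1.0:
        raise ValueError(
            f"infeasible inputs: split yields probabilities "
            f"({p_primary:.4g}, {p_secondary:.4g}) outside [0, 1]"
        )
    return p_primary, p_secondary


def apply_hazard_ratio(p_control: float, hr: float, method: str = "rate") -> float:
    """Apply a treatment-effect hazard ratio to a control-arm probability.

    The default rate-scale form ``1 - (1 - p)^hr`` preserves [0, 1) support
    and matches the proportional-hazards interpretation; ``method=
    "probability"`` multiplies the probability directly (clipped at 1) for
    convention-matching against spreadsheet implementations.
    """
    if not (0.0 <= p_control < 1.0):
        raise ValueError(f"control probability {p_control} outside [0, 1)")
    if hr < 0:
        raise ValueError("hazard ratio must be >= 0")
    if hr == 1.0:  # exact null effect, bit-for-bit
        return p_control
    if method == "rate":
        return 1.0 - (1.0 - p_control) ** hr
    if method == "probability":
        return min(p_control * hr, 1.0)
    raise ValueError(f"unknown hazard-ratio application method {method!r}")


def escalate_risk(p_base: float, cycle_index: int, growth: float) -> float:
    """Escalate an annual probability for cycle ``cycle_index`` (1-based).

    The base probability is converted to a rate, the rate is multiplied by
    ``growth**(cycle_index - 1)``, and the result converted back; cycle 1
    is returned unchanged and the output is always < 1.
    """
    if not (0.0 <= p_base < 1.0):
        raise ValueError(f"probability {p_base} outside [0, 1)")
    if cycle_index < 1:
        raise ValueError("cycle index is 1-based")
    if growth <= 0:
        raise ValueError("growth factor must be positive")
    if cycle_index == 1 or p_base == 0.0:
        return p_base
    rate = -math.log1p(-p_base)
    p = -math.expm1(-rate * growth ** (cycle_index - 1))
    # the rate is finite, so the probability is strictly below 1; keep it
    # that way even where floating point would round up
    return min(p, math.nextafter(1.0, 0.0))


def build_cycle_probabilities(
    params: ParameterSet,
    arm: str,
    setting: str | None = None,
    horizon: int | None = None,
) -> pd.DataFrame:
    """Per-cycle annual event probabilities for one arm.

    Returns a DataFrame indexed by cycle (1..horizon) with MultiIndex
    columns (state, event) covering both alive states: primary-prevention
    patients who acquire CVD are thereafter governed by the with-CVD risks
    (and, in the combination arm, by the drug's secondary-prevention hazard
    ratios).  Treatment-effect hazard ratios are applied to the baseline
    probability before escalation; cardiovascular events escalate with the
    CVD growth factor, non-CVD death with the non-CVD factor.
    """
    if arm not in (ARM_STATIN, ARM_COMBINATION):
        raise ParameterError([f"unknown arm {arm!r}; expected {ARM_STATIN!r} or "
                              f"{ARM_COMBINATION!r}"])
    setting = setting or params.setting
    horizon = int(horizon or params.settings.time_horizon)
    s = params.settings

    # arm-specific annual baseline (cycle 1) per state and event
    base: dict[tuple[str, str], float] = {}
    for state in ALIVE_STATES:
        baseline = params.baseline.for_state(state)
        hr_set = params.hr_for_state(state) if arm == ARM_COMBINATION else None
        for event in EVENTS:
            p = baseline[event]
            if hr_set is not None:
                p = apply_hazard_ratio(p, hr_set.hazard_ratios[event].value,
                                       method=s.hr_application)
            base[(state, event)] = p

    cycles = np.arange(1, horizon + 1)
    data = {
        (state, event): [
            escalate_risk(
                base[(state, event)],
                int(c),
                s.cvd_risk_growth if event in CVD_EVENTS else s.noncvd_risk_growth,
            )
            for c in cycles
        ]
        for state in ALIVE_STATES
        for event in EVENTS
    }
    table = pd.DataFrame(data, index=pd.Index(cycles, name="cycle"))
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["state", "event"])
    return table
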