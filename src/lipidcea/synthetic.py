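"""Synthetic cardiovascular outcome trials with known ground truth.

Emulates the arm-level summary data the derivation pipeline consumes: for
each of the six event types, per-arm event counts over a median follow-up,
in a mixed population where a stated fraction has established CVD and
events are a stated factor more likely in the CVD subgroup.  Because the
ground truth is known, the full derivation chain (annualize → prevalence
split → hazard-ratio application) can be checked end to end.

Event counts are drawn as independent binomials per event type; the
downstream model consumes marginal probabilities only, so within-patient
correlation between event types is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .epi import annualize_probability, apply_hazard_ratio, compound_probability
from .parameters import (
    EVENTS,
    Estimate,
    ParameterSet,
    load_parameters,
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated trial population.

    ``p_annual_without_cvd`` are annual statin-arm event probabilities for
    participants without established CVD; the with-CVD subgroup's risks are
    ``rr_cvd_vs_noncvd`` times larger (on the probability scale).  ``hr``
    is the true treatment effect per event, applied on the rate scale.
    """

    p_annual_without_cvd: Mapping[str, float]
    hr: Mapping[str, float]
    prevalence_cvd: float
    rr_cvd_vs_noncvd: float
    n_per_arm: int
    followup_years: float
    seed: int = 0

    def __post_init__(self) -> None:
        for ev, p in self.p_annual_without_cvd.items():
            if not (0.0 <= p < 1.0):
                raise ValueError(f"truth probability {ev}={p} outside [0, 1)")
        if not (0.0 < self.prevalence_cvd < 1.0):
            raise ValueError("prevalence must be strictly inside (0, 1)")
        if self.rr_cvd_vs_noncvd <= 0:
            raise ValueError("relative risk must be positive")

    def p_annual_with_cvd(self, event: str) -> float:
        p = self.rr_cvd_vs_noncvd * self.p_annual_without_cvd[event]
        if p >= 1.0:
            raise ValueError(f"with-CVD probability for {event} reaches 1")
        return p

    def p_annual_mixed(self, event: str, arm: str = "control") -> float:
        """Whole-population annual probability, the quantity a trial's
        arm-level outcome row reflects."""
        pi = self.prevalence_cvd
        p = (1 - pi) * self.p_annual_without_cvd[event] + pi * self.p_annual_with_cvd(event)
        if arm == "treatment":
            p = apply_hazard_ratio(p, self.hr[event])
        return p


@dataclass(frozen=True)
class TrialOutcome:
    """Arm-level results of one (synthetic or transcribed) outcome trial."""

    trial: str
    n_per_arm: Mapping[str, int]                   # control / treatment
    events: Mapping[str, Mapping[str, int]]        # arm -> event -> count
    followup_years: float
    prevalence_cvd: float
    composite_by_subgroup: Mapping[str, float]     # cvd / non_cvd proportions
    rr_cvd_vs_noncvd: float

    def proportion(self, arm: str, event: str) -> float:
        return self.events[arm][event] / self.n_per_arm[arm]


def simulate_trial(truth: SyntheticTruth, rng: np.random.Generator | None = None) -> TrialOutcome:
    """Draw one trial's arm-level event counts from the ground truth.

    Each arm/event count is binomial with success probability equal to the
    annual mixed-population probability compounded over follow-up.  The
    composite (any non-fatal MI / stroke / CVD death) proportions are
    reported per CVD subgroup of the control arm, consistent with the
    prevalence and relative risk.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    T = truth.followup_years
    n = truth.n_per_arm

    events: dict[str, dict[str, int]] = {}
    for arm in ("control", "treatment"):
        events[arm] = {
            ev: int(rng.binomial(n, compound_probability(truth.p_annual_mixed(ev, arm), T)))
            for ev in EVENTS
        }

    composite_events = ("nonfatal_mi", "nonfatal_stroke", "cvd_death")
    # union of independent per-event risks within each subgroup
    def composite(p_lookup) -> float:
        q = 1.0
        for ev in composite_events:
            q *= 1.0 - compound_probability(p_lookup(ev), T)
        return 1.0 - q

    comp_non_cvd = composite(lambda ev: truth.p_annual_without_cvd[ev])
    comp_cvd = composite(truth.p_annual_with_cvd)
    n_cvd = int(round(n * truth.prevalence_cvd))
    n_non = n - n_cvd
    comp = {
        "cvd": rng.binomial(n_cvd, comp_cvd) / n_cvd,
        "non_cvd": rng.binomial(n_non, comp_non_cvd) / n_non,
    }
    return TrialOutcome(
        trial="synthetic",
        n_per_arm={"control": n, "treatment": n},
        events=events,
        followup_years=T,
        prevalence_cvd=truth.prevalence_cvd,
        composite_by_subgroup=comp,
        rr_cvd_vs_noncvd=truth.rr_cvd_vs_noncvd,
    )


def recover_probabilities(trial: TrialOutcome) -> dict[str, dict[str, float]]:
    """Run the derivation pipeline on trial output: annualize the observed
    control-arm proportions, then split them by CVD prevalence and relative
    risk into per-state annual probabilities."""
    from .epi import split_by_prevalence

    out = {"without_cvd": {}, "with_cvd": {}, "hr": {}}
    for ev in EVENTS:
        p_all = annualize_probability(trial.proportion("control", ev), trial.followup_years)
        p_primary, p_secondary = split_by_prevalence(
            p_all, trial.prevalence_cvd, trial.rr_cvd_vs_noncvd)
        out["without_cvd"][ev] = p_primary
        out["with_cvd"][ev] = p_secondary
        # observed HR estimate on the rate scale
        p_t = annualize_probability(trial.proportion("treatment", ev), trial.followup_years)
        if p_all > 0 and p_t > 0:
            out["hr"][ev] = np.log1p(-p_t) / np.log1p(-p_all)
        else:
            out["hr"][ev] = np.nan
    return out


# ---------------------------------------------------------------------------
# Ready-made parameter fixtures


def make_fixture_parameters(
    profile: str = "paper_like", seed: int = 0, setting: str = "secondary"
) -> ParameterSet:
    """Deterministic parameter sets for testing and demonstrations.

    paper_like
        The shipped configuration (published hazard ratios, utilities and
        costs with synthetic baseline probabilities of realistic magnitude)
        for icosapent ethyl.
    stress
        Boundary values: large baseline probabilities, hazard ratios at
        their CI extremes, maximal escalation — exercises renormalization
        and support-boundary handling.
    null
        Hazard ratio 1 for every event and a zero price premium: both arms
        must behave identically.
    """
    if profile == "paper_like":
        return load_parameters(drug="icosapent_ethyl", setting=setting)

    base = load_parameters(drug="icosapent_ethyl", setting=setting)
    if profile == "null":
        ps = base.deepcopy()
        for s, hr_set in ps.hazard_ratios.items():
            unit = {ev: Estimate(1.0, 1.0, 1.0) for ev in EVENTS}
            object.__setattr__(hr_set, "hazard_ratios", unit)
        object.__setattr__(ps.costs, "annual_drug_cost", 0.0)
        return ps
    if profile == "stress":
        rng = np.random.default_rng(seed)
        ps = base.deepcopy()
        for s, hr_set in ps.hazard_ratios.items():
            extreme = {
                ev: Estimate(est.low if rng.random() < 0.5 else est.high,
                             est.low, est.high)
                for ev, est in hr_set.hazard_ratios.items()
            }
            object.__setattr__(hr_set, "hazard_ratios", extreme)
        big_wo = {ev: 0.15 for ev in EVENTS}
        big_wc = {ev: 0.30 for ev in EVENTS}
        object.__setattr__(ps.baseline, "without_cvd", big_wo)
        object.__setattr__(ps.baseline, "with_cvd", big_wc)
        return ps
    raise ValueError(f"unknown fixture profile {profile!r}")
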