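"""Probabilistic sensitivity analysis.

Each draw jointly samples every uncertain input from its distribution
(normal hazard ratios truncated at a small positive floor, beta utilities
and baseline probabilities, gamma decrements and costs), re-runs the
two-arm model, and records the incremental outcomes.  Drug prices, the
discount rate, and the risk-escalation factors are fixed.

Draw *i* is generated from an rng seeded with ``(seed, i)``, so individual
draws are reproducible and independent of the total iteration count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .econ import compare_arms
from .parameters import (
    AGE_BANDS,
    ALIVE_STATES,
    EVENTS,
    Estimate,
    NONFATAL_EVENTS,
    ParameterSet,
)


def _sampled_estimate(est: Estimate, draw: float) -> Estimate:
    return Estimate(draw, min(draw, est.low), max(draw, est.high))


def sample_parameter_set(
    params: ParameterSet, rng: np.random.Generator, width_scale: float = 1.0
) -> ParameterSet:
    """One joint draw of all uncertain parameters.

    ``width_scale`` shrinks every distribution's spread around its mean
    (0 collapses all distributions to the base case); used to test
    convergence of the PSA mean to the deterministic result.

    Sampling is independent across parameters.  If a drawn with-CVD state
    utility exceeds the drawn without-CVD utility for the same age band it
    is capped there, preserving the ordering the states require.
    """
    ps = params.deepcopy()

    def draw(spec) -> float:
        x = spec.sample(rng)
        return spec.mean + width_scale * (x - spec.mean) if width_scale != 1.0 else x

    # hazard ratios
    scale = ps.settings.hr_sampling_scale
    for setting, hr_set in ps.hazard_ratios.items():
        sampled = {
            ev: _sampled_estimate(hr_set.hazard_ratios[ev],
                                  max(draw(hr_set.distribution(ev, scale)), 1e-6))
            for ev in EVENTS
        }
        object.__setattr__(ps.hazard_ratios[setting], "hazard_ratios", sampled)

    # utilities: beta state values (ordering enforced), gamma decrements
    without, with_ = {}, {}
    for band in AGE_BANDS:
        wo = params.utilities.without_cvd[band]
        wc = params.utilities.with_cvd[band]
        wo_draw = min(draw(_beta_spec(wo)), 1.0)
        wc_draw = min(draw(_beta_spec(wc)), wo_draw)
        without[band] = _sampled_estimate(wo, wo_draw)
        with_[band] = _sampled_estimate(wc, wc_draw)
    decr = {
        ev: _sampled_estimate(params.utilities.decrements[ev],
                              max(draw(_gamma_spec(params.utilities.decrements[ev])), 0.0))
        for ev in NONFATAL_EVENTS
    }
    object.__setattr__(ps.utilities, "without_cvd", without)
    object.__setattr__(ps.utilities, "with_cvd", with_)
    object.__setattr__(ps.utilities, "decrements", decr)

    # costs: gamma for state/event/death costs; prices stay fixed
    for attr in ("annual_state", "event", "death"):
        block = getattr(params.costs, attr)
        sampled = {
            k: _sampled_estimate(v, max(draw(_gamma_spec(v)), 0.0))
            for k, v in block.items()
        }
        object.__setattr__(ps.costs, attr, sampled)

    # baseline statin-arm probabilities: beta around the point value
    for state in ALIVE_STATES:
        attr = "without_cvd" if state == "alive_without_cvd" else "with_cvd"
        sampled = {
            ev: min(max(draw(params.baseline.distribution(state, ev)), 0.0), 0.999999)
            for ev in EVENTS
        }
        object.__setattr__(ps.baseline, attr, sampled)

    return ps


def _beta_spec(est: Estimate):
    from .parameters import ci_to_distribution

    if est.high == est.low:
        from .parameters import DistributionSpec
        return DistributionSpec("fixed", est.value, {})
    return ci_to_distribution(est.value, est.low, est.high, "beta")


def _gamma_spec(est: Estimate):
    from .parameters import ci_to_distribution

    if est.high == est.low or est.value == 0:
        from .parameters import DistributionSpec
        return DistributionSpec("fixed", est.value, {})
    return ci_to_distribution(est.value, est.low, est.high, "gamma")


@dataclass
class PsaResult:
    """Per-draw incremental outcomes plus summary statistics.

    ``mean_icer`` is the arithmetic mean of per-draw ICERs (signs of
    cost-saving draws retained); ``icer_ratio_of_means`` is the alternative
    mean-ΔC over mean-ΔQ summary, reported for transparency.
    """

    drug: str
    setting: str
    seed: int
    iterations: int
    draws: pd.DataFrame
    mean_icer: float
    icer_ci: tuple[float, float]
    mean_delta_qaly: float
    delta_qaly_ci: tuple[float, float]
    mean_delta_cost: float
    icer_ratio_of_means: float
    n_resampled: int = 0


def run_psa(
    params: ParameterSet,
    iterations: int | None = None,
    seed: int = 0,
    width_scale: float = 1.0,
) -> PsaResult:
    """Monte-Carlo propagation of joint parameter uncertainty.

    One full two-arm model evaluation per draw.  A draw whose sampled
    inputs fail validation is replaced by a fresh draw from a follow-on
    stream; the number of replacements is recorded.
    """
    n = int(iterations if iterations is not None else params.settings.psa_iterations)
    records = []
    n_resampled = 0
    for i in range(n):
        for attempt in range(100):
            rng = np.random.default_rng([seed, i, attempt])
            try:
                sampled = sample_parameter_set(params, rng, width_scale=width_scale)
                res = compare_arms(sampled)
                break
            except (ValueError, KeyError):
                n_resampled += 1
        else:  # pragma: no cover - would need pathologically wide inputs
            raise RuntimeError(f"draw {i}: no valid parameter sample in 100 attempts")
        records.append({
            "draw": i,
            "delta_cost": res.delta_cost,
            "delta_qaly": res.delta_qaly,
            "delta_ly": res.delta_ly,
            "icer": res.icer_per_qaly if res.icer_per_qaly is not None else np.nan,
        })
    draws = pd.DataFrame.from_records(records)
    icers = draws["icer"].dropna()
    lo, hi = np.percentile(icers, [2.5, 97.5]) if len(icers) else (np.nan, np.nan)
    qlo, qhi = np.percentile(draws["delta_qaly"], [2.5, 97.5])
    mean_dq = float(draws["delta_qaly"].mean())
    mean_dc = float(draws["delta_cost"].mean())
    return PsaResult(
        drug=params.drug,
        setting=params.setting,
        seed=seed,
        iterations=n,
        draws=draws,
        mean_icer=float(icers.mean()) if len(icers) else np.nan,
        icer_ci=(float(lo), float(hi)),
        mean_delta_qaly=mean_dq,
        delta_qaly_ci=(float(qlo), float(qhi)),
        mean_delta_cost=mean_dc,
        icer_ratio_of_means=mean_dc / mean_dq if mean_dq != 0 else np.nan,
        n_resampled=n_resampled,
    )


@dataclass
class CeacCurve:
    """Cost-effectiveness acceptability curve on a willingness-to-pay grid.

    ``probability[k]`` is the fraction of draws with positive net monetary
    benefit at ``wtp[k]``; ``lambda_star`` is the smallest grid value where
    it reaches 95% (None if never reached).
    """

    wtp: np.ndarray
    probability: np.ndarray
    lambda_star: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp_eur_per_qaly": self.wtp,
                             "prob_cost_effective": self.probability})


def ceac(
    psa: PsaResult,
    wtp_grid: np.ndarray | None = None,
    threshold: float = 0.95,
) -> CeacCurve:
    """Acceptability of the combination vs statin across WTP values."""
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 200_000.0 + 500.0, 1_000.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    dq = psa.draws["delta_qaly"].to_numpy()
    dc = psa.draws["delta_cost"].to_numpy()
    nmb = wtp_grid[:, None] * dq[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    above = np.nonzero(prob >= threshold)[0]
    lam = float(wtp_grid[above[0]]) if len(above) else None
    return CeacCurve(wtp=wtp_grid, probability=prob, lambda_star=lam)
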