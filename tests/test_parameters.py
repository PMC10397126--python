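"""Parameter loading, validation, distribution construction, serialization."""

import math

import numpy as np
import pytest

from lipidcea import (
    DistributionSpec,
    ParameterError,
    ParameterSet,
    UnsupportedSettingError,
    ci_to_distribution,
    load_parameters,
)


class TestLoadParameters:
    def test_icosapent_secondary_values(self, params_icosapent_secondary):
        ps = params_icosapent_secondary
        mi = ps.hazard_ratios["secondary"].hazard_ratios["nonfatal_mi"]
        assert (mi.value, mi.low, mi.high) == (0.68, 0.58, 0.79)
        assert ps.costs.annual_drug_cost == 2400.0
        assert ps.trial == "REDUCE-IT"

    def test_unsupported_primary_combinations(self):
        for drug in ("ezetimibe", "evolocumab", "alirocumab"):
            with pytest.raises(UnsupportedSettingError):
                load_parameters(drug=drug, setting="primary")

    def test_fibrate_annual_cost(self, params_fibrate_secondary):
        assert params_fibrate_secondary.costs.annual_drug_cost == 130.44

    def test_unknown_drug_lists_available(self):
        with pytest.raises(ParameterError, match="unknown drug"):
            load_parameters(drug="nonexistent", setting="secondary")

    def test_statin_cost_shared(self, params_icosapent_secondary):
        assert params_icosapent_secondary.costs.annual_statin_cost == 131.62


# digit-for-digit regression of the shipped fixture against the published
# input table (hazard ratios as printed; costs in 2021 euros)
PUBLISHED_SECONDARY_HRS = {
    "icosapent_ethyl": {
        "nonfatal_mi": (0.68, 0.58, 0.79), "cvd_death": (0.79, 0.67, 0.91),
        "noncvd_death": (1.01, 0.85, 1.16), "nonfatal_stroke": (0.71, 0.60, 0.82),
        "unstable_angina_hosp": (0.67, 0.57, 0.77), "coronary_revasc": (0.66, 0.56, 0.75),
    },
    "evolocumab": {
        "nonfatal_mi": (0.72, 0.64, 0.81), "cvd_death": (1.05, 0.88, 1.25),
        "noncvd_death": (1.04, 0.91, 1.19), "nonfatal_stroke": (0.91, 0.78, 1.07),
        "unstable_angina_hosp": (0.99, 0.82, 1.18), "coronary_revasc": (0.78, 0.71, 0.86),
    },
    "alirocumab": {
        "nonfatal_mi": (0.86, 0.77, 0.96), "cvd_death": (0.88, 0.74, 1.05),
        "noncvd_death": (0.78, 0.66, 0.94), "nonfatal_stroke": (0.73, 0.57, 0.93),
        "unstable_angina_hosp": (0.61, 0.41, 0.92), "coronary_revasc": (0.88, 0.79, 0.97),
    },
    "ezetimibe": {
        "nonfatal_mi": (0.87, 0.80, 0.95), "cvd_death": (1.00, 0.89, 1.13),
        "noncvd_death": (0.98, 0.90, 1.06), "nonfatal_stroke": (0.86, 0.73, 1.00),
        "unstable_angina_hosp": (1.06, 0.85, 1.33), "coronary_revasc": (0.96, 0.90, 1.02),
    },
}
PUBLISHED_COSTS = {
    "alive_without_cvd": 4522, "alive_with_cvd": 8008, "nonfatal_mi": 8588,
    "nonfatal_stroke": 10441, "unstable_angina_hosp": 4791, "coronary_revasc": 9901,
    "cvd_death": 11842, "noncvd_death": 3924,
}
PUBLISHED_UTILITIES = {
    ("without_cvd", "age_65_70"): (0.65, 0.64, 0.67),
    ("without_cvd", "age_70_plus"): (0.63, 0.62, 0.65),
    ("with_cvd", "age_65_70"): (0.57, 0.56, 0.59),
    ("with_cvd", "age_70_plus"): (0.55, 0.54, 0.57),
}


@pytest.mark.parametrize("drug", sorted(PUBLISHED_SECONDARY_HRS))
def test_fixture_matches_published_hazard_ratios(drug):
    ps = load_parameters(drug=drug, setting="secondary")
    for event, expected in PUBLISHED_SECONDARY_HRS[drug].items():
        est = ps.hazard_ratios["secondary"].hazard_ratios[event]
        assert (est.value, est.low, est.high) == pytest.approx(expected)


def test_fixture_matches_published_costs_and_utilities(params_icosapent_secondary):
    ps = params_icosapent_secondary
    assert ps.costs.annual_state["alive_without_cvd"].value == PUBLISHED_COSTS["alive_without_cvd"]
    assert ps.costs.annual_state["alive_with_cvd"].value == PUBLISHED_COSTS["alive_with_cvd"]
    for ev in ("nonfatal_mi", "nonfatal_stroke", "unstable_angina_hosp", "coronary_revasc"):
        assert ps.costs.event[ev].value == PUBLISHED_COSTS[ev]
    assert ps.costs.death["cvd_death"].value == PUBLISHED_COSTS["cvd_death"]
    assert ps.costs.death["noncvd_death"].value == PUBLISHED_COSTS["noncvd_death"]
    for (group, band), expected in PUBLISHED_UTILITIES.items():
        block = ps.utilities.without_cvd if group == "without_cvd" else ps.utilities.with_cvd
        assert (block[band].value, block[band].low, block[band].high) == pytest.approx(expected)
    assert ps.utilities.decrements["nonfatal_stroke"].value == 0.12
    assert ps.settings.discount_rate == 0.03
    assert ps.settings.cvd_risk_growth == 1.14
    assert ps.settings.noncvd_risk_growth == 1.10


class TestCiToDistribution:
    def test_normal_scale_from_ci(self):
        spec = ci_to_distribution(0.68, 0.58, 0.79, "normal")
        assert spec.params["scale"] == pytest.approx((0.79 - 0.58) / (2 * 1.959964), rel=1e-6)
        assert spec.params["scale"] == pytest.approx(0.0536, abs=2e-4)

    def test_fixed_degenerate(self):
        spec = ci_to_distribution(0.65, 0.65, 0.65, "fixed")
        rng = np.random.default_rng(0)
        assert spec.sample(rng) == 0.65
        assert np.all(spec.sample(rng, 10) == 0.65)

    def test_gamma_pct25_percentile_span(self):
        # ±25% treated as a 95% interval: fitted gamma quantiles must sit
        # close to mean*(1∓0.25) (independent numerical check via scipy)
        from scipy import stats

        spec = ci_to_distribution(4522, 3391.5, 5652.5, "gamma")
        dist = stats.gamma(spec.params["shape"], scale=spec.params["scale"])
        assert dist.mean() == pytest.approx(4522, rel=1e-12)
        # the gamma is right-skewed, so each endpoint sits slightly above
        # the symmetric target; the overall span matches ±25% closely
        q025, q975 = dist.ppf([0.025, 0.975])
        assert q025 == pytest.approx(3391.5, rel=0.03)
        assert q975 == pytest.approx(5652.5, rel=0.03)
        assert q975 - q025 == pytest.approx(2 * 0.25 * 4522, rel=0.02)

    def test_beta_moments(self):
        spec = ci_to_distribution(0.65, 0.64, 0.67, "beta")
        a, b = spec.params["alpha"], spec.params["beta"]
        assert a / (a + b) == pytest.approx(0.65, rel=1e-12)

    def test_support_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            ci_to_distribution(4522, 3391.5, 5652.5, "beta")  # cost is not in [0,1]
        with pytest.raises(ParameterError):
            ci_to_distribution(-1.0, -2.0, 0.0, "gamma")

    def test_ci_must_bracket_mean(self):
        with pytest.raises(ParameterError):
            ci_to_distribution(0.5, 0.6, 0.7, "normal")


@pytest.mark.parametrize(
    "spec",
    [
        ci_to_distribution(0.68, 0.58, 0.79, "normal"),
        ci_to_distribution(0.68, 0.58, 0.79, "lognormal"),
        ci_to_distribution(0.65, 0.64, 0.67, "beta"),
        ci_to_distribution(4522, 3391.5, 5652.5, "gamma"),
        ci_to_distribution(0.03, 0.03, 0.03, "fixed"),
    ],
    ids=lambda s: s.family,
)
def test_sampling_reproduces_mean(spec):
    """10^5 draws recover the stated mean within 3 Monte-Carlo SEs.

    The lognormal spec is located at the point estimate as its median, so
    its arithmetic mean carries the usual exp(sigma^2/2) factor.
    """
    rng = np.random.default_rng(7)
    draws = np.asarray(spec.sample(rng, 100_000), dtype=float)
    expected = spec.mean
    if spec.family == "lognormal":
        expected = math.exp(spec.params["mu"] + spec.params["sigma"] ** 2 / 2)
    se = draws.std(ddof=1) / math.sqrt(len(draws))
    assert abs(draws.mean() - expected) < max(3 * se, 1e-12)


def test_parameter_set_serialization_roundtrip(params_icosapent_secondary):
    text = params_icosapent_secondary.to_json()
    restored = ParameterSet.from_json(text)
    assert restored == params_icosapent_secondary
    assert restored.to_json() == text


def test_truncated_normal_respects_floor():
    spec = DistributionSpec("normal", 0.05, {"loc": 0.05, "scale": 0.5}, truncate_low=1e-6)
    draws = spec.sample(np.random.default_rng(3), 5000)
    assert np.all(draws >= 1e-6)
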