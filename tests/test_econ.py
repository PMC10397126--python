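"""Incremental analysis: ICERs, NNT, frontier, tornado, scenarios, pricing."""

import dataclasses
import itertools

import numpy as np
import pytest

from lipidcea import (
    ARM_COMBINATION,
    ARM_STATIN,
    CEResult,
    ScenarioOverrides,
    compare_arms,
    efficiency_frontier,
    load_parameters,
    nnt,
    one_way_sensitivity,
    price_threshold,
    run_cohort,
    scenario_analysis,
)
from lipidcea.econ import _dominance, compare_traces
from lipidcea.synthetic import make_fixture_parameters


def make_result(drug, dq, dc):
    return CEResult(drug=drug, setting="secondary", delta_qaly=dq, delta_ly=dq,
                    delta_cost=dc, icer_per_qaly=dc / dq if dq else None,
                    icer_per_ly=None, dominance=_dominance(dc, dq))


class TestCompareArms:
    def test_exact_division(self):
        r = make_result("x", 4.0, 100.0)
        assert r.icer_per_qaly == 25.0
        assert r.dominance == "tradeoff"

    def test_null_treatment_undefined_icer(self):
        res = compare_arms(make_fixture_parameters("null"))
        assert res.delta_qaly == pytest.approx(0.0, abs=1e-12)
        assert res.delta_cost == pytest.approx(0.0, abs=1e-9)
        assert res.icer_per_qaly is None

    def test_icer_consistent_with_increments(self, params_icosapent_secondary):
        res = compare_arms(params_icosapent_secondary)
        assert res.icer_per_qaly == pytest.approx(res.delta_cost / res.delta_qaly)
        assert res.icer_per_ly == pytest.approx(res.delta_cost / res.delta_ly)
        assert res.delta_qaly > 0  # protective HRs, higher-priced therapy
        assert res.dominance == "tradeoff"


class TestNnt:
    def test_identical_traces_undefined(self, params_icosapent_secondary):
        t = run_cohort(params_icosapent_secondary, ARM_STATIN)
        assert nnt(t, t, "nonfatal_mi") is None

    def test_simple_ratio(self, params_icosapent_secondary):
        control = run_cohort(params_icosapent_secondary, ARM_STATIN)
        treat = run_cohort(params_icosapent_secondary, ARM_COMBINATION)
        diff = (control.totals["ev_nonfatal_mi"] - treat.totals["ev_nonfatal_mi"])
        assert nnt(treat, control, "nonfatal_mi") == pytest.approx(1.0 / diff)

    def test_unknown_event_rejected(self, params_icosapent_secondary):
        t = run_cohort(params_icosapent_secondary, ARM_STATIN)
        with pytest.raises(KeyError):
            nnt(t, t, "heart_failure")


def brute_force_frontier(points):
    """Oracle: a point is off the frontier iff another point, or a convex
    blend of two points, weakly dominates it (pairwise enumeration)."""
    status = {}
    for i, (li, qi, ci) in enumerate(points):
        dominated = False
        for j, (lj, qj, cj) in enumerate(points):
            if i != j and qj >= qi and cj <= ci and (qj > qi or cj < ci):
                dominated = True
        if not dominated:
            for (la, qa, ca), (lb, qb, cb) in itertools.permutations(
                    [p for k, p in enumerate(points) if k != i], 2):
                if qa == qb or not (min(qa, qb) <= qi <= max(qa, qb)):
                    continue
                w = (qi - qa) / (qb - qa)
                if not (0 <= w <= 1):
                    continue
                if ca + w * (cb - ca) < ci - 1e-12:
                    dominated = True
                    break
        status[li] = not dominated
    return status


class TestEfficiencyFrontier:
    def test_single_dominant_strategy(self):
        pts = efficiency_frontier([make_result("a", 1.0, -10.0)])
        by_label = {p.label: p for p in pts}
        assert by_label["a"].on_frontier
        assert by_label["statin"].status == "dominated"

    def test_same_qaly_higher_cost_dominated(self):
        pts = efficiency_frontier([make_result("a", 1.0, 10.0),
                                   make_result("b", 1.0, 20.0)])
        by_label = {p.label: p for p in pts}
        assert by_label["a"].on_frontier
        assert by_label["b"].status == "dominated"

    def test_extended_dominance(self):
        # b lies above the segment from origin to c
        pts = efficiency_frontier([make_result("b", 1.0, 100.0),
                                   make_result("c", 2.0, 120.0)])
        by_label = {p.label: p for p in pts}
        assert by_label["b"].status == "extended_dominated"
        assert by_label["c"].on_frontier

    def test_matches_brute_force_on_secondary_fixtures(self, all_secondary_params):
        results = [compare_arms(p) for p in all_secondary_params]
        pts = efficiency_frontier(results)
        oracle = brute_force_frontier(
            [("statin", 0.0, 0.0)] + [(r.drug, r.delta_qaly, r.delta_cost)
                                      for r in results])
        for p in pts:
            assert p.on_frontier == oracle[p.label], p.label

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            results = [
                make_result(f"s{k}", float(rng.normal(0.5, 0.5)),
                            float(rng.normal(5000, 20000)))
                for k in range(5)
            ]
            pts = efficiency_frontier(results)
            oracle = brute_force_frontier(
                [("statin", 0.0, 0.0)] + [(r.drug, r.delta_qaly, r.delta_cost)
                                          for r in results])
            for p in pts:
                assert p.on_frontier == oracle[p.label], (trial, p.label)


class TestOneWaySensitivity:
    def test_null_treatment_all_finite_spreads_zero(self):
        entries = one_way_sensitivity(
            make_fixture_parameters("null"),
            bounds=None,
        )
        for e in entries:
            if e.icer_at_low is None or e.icer_at_high is None:
                continue  # ICER undefined at zero QALY increment
            assert e.spread == pytest.approx(0.0, abs=1e-6)

    def test_cvd_death_inputs_among_largest(self, params_icosapent_secondary):
        """Variation in CVD-death cost and baseline probability must rank
        among the most influential parameters."""
        entries = one_way_sensitivity(params_icosapent_secondary)
        finite = [e for e in entries if np.isfinite(e.spread)]
        names_top = {e.parameter for e in finite[:10]}
        assert any("cvd_death" in n for n in names_top)
        spread_map = {e.parameter: e.spread for e in finite}
        assert spread_map["cost_death_cvd_death"] > 0

    def test_hr_bounds_ordering_consistent(self, params_icosapent_secondary):
        """A lower MI hazard ratio (more protection) cannot produce a worse
        ICER than the upper bound, given a positive QALY increment."""
        entries = {e.parameter: e for e in one_way_sensitivity(params_icosapent_secondary)}
        e = entries["hr_secondary_nonfatal_mi"]
        assert e.icer_at_low < e.icer_at_high


class TestScenarioAnalysis:
    def test_noop_override_matches_basecase(self, params_icosapent_secondary):
        base = compare_arms(params_icosapent_secondary)
        scen = scenario_analysis(params_icosapent_secondary, ScenarioOverrides())
        assert scen == base

    def test_price_multiplier_moves_icer_linearly(self, params_icosapent_secondary):
        base = compare_arms(params_icosapent_secondary)
        up = scenario_analysis(params_icosapent_secondary,
                               ScenarioOverrides(price_multiplier=1.5))
        down = scenario_analysis(params_icosapent_secondary,
                                 ScenarioOverrides(price_multiplier=0.5))
        assert down.icer_per_qaly < base.icer_per_qaly < up.icer_per_qaly
        assert up.delta_qaly == pytest.approx(base.delta_qaly, abs=1e-12)
        # cost increments respond symmetrically to a symmetric price change
        assert (up.delta_cost - base.delta_cost) == pytest.approx(
            base.delta_cost - down.delta_cost, rel=1e-9)

    def test_longer_horizon_earlier_start(self, params_icosapent_primary):
        scen = scenario_analysis(
            params_icosapent_primary,
            ScenarioOverrides(start_age=55.0, time_horizon=25))
        assert scen.horizon == 25
        assert scen.delta_qaly > 0


class TestPriceThreshold:
    def test_fixed_point_at_current_icer(self, params_icosapent_secondary):
        base = compare_arms(params_icosapent_secondary)
        res = price_threshold(params_icosapent_secondary, base.icer_per_qaly)
        assert res.annual_price == pytest.approx(2400.0, abs=1e-6)

    def test_cost_neutral_price(self, params_icosapent_secondary):
        res = price_threshold(params_icosapent_secondary, 0.0)
        ps = params_icosapent_secondary.deepcopy()
        object.__setattr__(ps.costs, "annual_drug_cost", res.annual_price)
        assert compare_arms(ps).delta_cost == pytest.approx(0.0, abs=1e-3)

    def test_icer_increasing_in_price(self, params_icosapent_secondary):
        icers = []
        for mult in (0.5, 1.0, 2.0):
            icers.append(scenario_analysis(
                params_icosapent_secondary,
                ScenarioOverrides(price_multiplier=mult)).icer_per_qaly)
        assert icers == sorted(icers)

    def test_no_solution_without_qaly_gain(self):
        ps = make_fixture_parameters("null")
        res = price_threshold(ps, 10_000.0)
        assert res.annual_price is None

    def test_pcsk9_needs_large_discount_to_match_icosapent(self):
        """Reaching icosapent ethyl's secondary-prevention ICER requires a
        price cut of more than half of alirocumab's list price."""
        ico = compare_arms(load_parameters(drug="icosapent_ethyl", setting="secondary"))
        ali = load_parameters(drug="alirocumab", setting="secondary")
        res = price_threshold(ali, ico.icer_per_qaly)
        assert res.annual_price is not None
        assert res.annual_price < 0.5 * ali.costs.annual_drug_cost
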