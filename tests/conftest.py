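"""Shared fixtures and the individual-level microsimulation oracle.

The microsimulation replays the exact per-cycle probabilities and
competing-risk ordering of the cohort engine at the level of simulated
individuals; cohort expectations must agree with its Monte-Carlo averages
within sampling error.  It exists only as a test oracle.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from lipidcea import build_cycle_probabilities, load_parameters

hyp_settings.register_profile("suite", derandomize=True, max_examples=50)
hyp_settings.load_profile("suite")


@pytest.fixture(scope="session")
def params_icosapent_secondary():
    return load_parameters(drug="icosapent_ethyl", setting="secondary")


@pytest.fixture(scope="session")
def params_icosapent_primary():
    return load_parameters(drug="icosapent_ethyl", setting="primary")


@pytest.fixture(scope="session")
def params_fibrate_secondary():
    return load_parameters(drug="fibrate", setting="secondary")


@pytest.fixture(scope="session")
def all_secondary_params():
    drugs = ("icosapent_ethyl", "evolocumab", "alirocumab", "ezetimibe", "fibrate")
    return [load_parameters(drug=d, setting="secondary") for d in drugs]


def microsimulate(params, arm, n=100_000, seed=12345):
    """Individual-level replay of the cohort model.

    Returns per-individual undiscounted life years and cumulative non-fatal
    MI counts, using the same deaths-first competing-risk ordering as the
    cohort engine.
    """
    table = build_cycle_probabilities(params, arm)
    rng = np.random.default_rng(seed)
    horizon = params.settings.time_horizon
    # 0 = alive without CVD, 1 = alive with CVD, 2 = dead
    state = np.full(n, 0 if params.setting == "primary" else 1, dtype=np.int8)
    ly = np.zeros(n)
    mi = np.zeros(n)

    for t in range(1, horizon + 1):
        p = table.loc[t]
        start_state = state.copy()  # transitions act on cycle-start occupancy
        for code, sname in ((0, "alive_without_cvd"), (1, "alive_with_cvd")):
            idx = np.flatnonzero(start_state == code)
            if len(idx) == 0:
                continue
            d_cvd = p[(sname, "cvd_death")]
            d_non = p[(sname, "noncvd_death")]
            u = rng.random(len(idx))
            died = u < d_cvd + d_non
            state[idx[died]] = 2
            alive = idx[~died]
            v = rng.random(len(alive))
            p_mi = p[(sname, "nonfatal_mi")]
            p_st = p[(sname, "nonfatal_stroke")]
            had_mi = v < p_mi
            had_stroke = (v >= p_mi) & (v < p_mi + p_st)
            mi[alive[had_mi]] += 1
            if code == 0:
                state[alive[had_mi | had_stroke]] = 1
        ly += state != 2
    return ly, mi
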