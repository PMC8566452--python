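"""Shared fixtures.

The desk-scale passage scenario (and its calibrated blank-channel flow)
is expensive to build, so one simulator instance is shared session-wide;
individual passage runs are memoised on (params, μ_f, flow rate).
"""

from __future__ import annotations

import numpy as np
import pytest

from cellsqueeze.fixtures import (
    GENERATING_MU_F,
    GENERATING_PARAMS,
    coarse_scenario,
    make_passage_table,
    passage_simulator,
)
from cellsqueeze.forces import ElasticParams
from cellsqueeze.mesh import build_icosphere, compute_rest_state


@pytest.fixture(scope="session")
def scenario():
    return coarse_scenario(seed=0)


@pytest.fixture(scope="session")
def simulator(scenario):
    sim = passage_simulator(scenario)
    sim._memo = {}

    def cached(params, mu_f, flow_rate):
        if isinstance(params, ElasticParams):
            key_p = tuple(params.as_array())
        else:
            key_p = tuple(np.asarray(params, dtype=float))
            params = ElasticParams.from_array(params)
        key = (key_p, float(mu_f), float(flow_rate))
        if key not in sim._memo:
            sim._memo[key] = sim.run(params, mu_f, flow_rate)
        return sim._memo[key]

    def cached_times(params, mu_f, flow_rate):
        """Memoised variant of the simulator's (entry, transit) contract."""
        res = cached(params, mu_f, flow_rate)
        et = np.nan if res.entry_time is None else res.entry_time
        tt = np.nan if res.transit_time is None else res.transit_time
        return et, tt

    sim.cached = cached
    sim.cached_times = cached_times
    return sim


@pytest.fixture(scope="session")
def passage_table(scenario, simulator):
    table, truth = make_passage_table(scenario, simulator=simulator)
    return table, truth


@pytest.fixture(scope="session")
def small_mesh():
    m = build_icosphere(2.0, 2)  # 162 nodes
    return m, compute_rest_state(m)


@pytest.fixture(scope="session")
def tiny_mesh():
    m = build_icosphere(1.0, 1)  # 42 nodes
    return m, compute_rest_state(m)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
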