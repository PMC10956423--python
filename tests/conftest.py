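"""Shared fixtures: landscapes and one reusable steered-pull ensemble."""

import numpy as np
import pytest
from hypothesis import settings

import tyrgate as tg

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")
from tyrgate.freenergy import build_workset, default_z_grid
from tyrgate.pullsim import (
    EquilibriumProtocol,
    PullProtocol,
    harvest_starting_points,
    simulate_equilibrium,
    simulate_pull,
)

KT = tg.thermal_energy()


@pytest.fixture(scope="session")
def symmetric_well():
    """The reference gate: wells 7 Å apart, 8 kcal/mol barrier, symmetric."""
    return tg.make_double_well(2.8, 9.8, barrier=8.0, asymmetry=0.0,
                               domain=(0.8, 11.8))


@pytest.fixture(scope="session")
def presets():
    return tg.isoform_presets()


def pull_ensemble(landscape, n_traces, seed, sites=("A", "B"), n_boot=None,
                  production_ns=20.0, spring=10.0):
    """Production run → harvest → pulls → WorkSet, per site."""
    out = {}
    for site in sites:
        prod = EquilibriumProtocol(duration=production_ns, n_runs=1, n_sites=1,
                                   seed=seed)
        trace = simulate_equilibrium(landscape, prod, landscape.x_down,
                                     run_id="production", site_id=site)
        starts = harvest_starting_points(trace, n_traces, production_ns / 2.0)
        protocol = PullProtocol(seed=seed, n_traces=n_traces, spring=spring)
        traces = [
            simulate_pull(landscape, protocol, x0, replicate_id=k, site_id=site,
                          z_start=landscape.x_down)
            for k, x0 in enumerate(starts)
        ]
        out[site] = traces
    all_traces = [t for ts in out.values() for t in ts]
    grid = default_z_grid(landscape.x_down, all_traces[0].protocol.displacement)
    return build_workset(all_traces, grid)


@pytest.fixture(scope="session")
def recovery_workset(symmetric_well):
    """100 pulls/site × 2 sites on the symmetric gate (the core recovery run)."""
    return pull_ensemble(symmetric_well, n_traces=100, seed=11)


@pytest.fixture(scope="session")
def recovery_reference(symmetric_well, recovery_workset):
    """Exact restrained profile matching the recovery ensemble."""
    return tg.exact_restrained_profile(
        symmetric_well, recovery_workset.z_grid, k_spring=10.0, kT=KT
    )
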