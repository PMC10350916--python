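import numpy as np
import pytest

from slmassembly import ModelParams, TargetSet, compact_targets


@pytest.fixture(scope="session")
def table1_params() -> ModelParams:
    """Reference system parameters (small step cap for test speed)."""
    return ModelParams(T_cap=200_000, record_every=100, seed=0)


@pytest.fixture(scope="session")
def table1_targets() -> TargetSet:
    return compact_targets(25, 2)


@pytest.fixture(scope="session")
def micro_params() -> ModelParams:
    """Two particles on a 3x3 torus with one stored target."""
    return ModelParams(N=2, L=3, M_T=1, T_cap=1000, record_every=10, seed=0)


@pytest.fixture(scope="session")
def micro_targets() -> TargetSet:
    return compact_targets(2, 1)


@pytest.fixture(scope="session")
def quick_trajectories(table1_targets):
    """A handful of short driven trajectories shared across tests."""
    from slmassembly import run_trajectory
    params = ModelParams(delta_mu=2.4, T_cap=4_000_000, record_every=100)
    return [run_trajectory(params, table1_targets, seed=300 + i)
            for i in range(6)]
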