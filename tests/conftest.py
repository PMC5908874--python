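import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clusternet as cn

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_spec() -> cn.NetworkSpec:
    """Reference parameter set: N_E=4000, N_I=1000, Q=20, g=1.2, m_X=0.03."""
    return cn.NetworkSpec()


@pytest.fixture(scope="session")
def small_spec() -> cn.NetworkSpec:
    """Small network for connectivity statistics (fast to realise)."""
    return cn.NetworkSpec(N_E=400, N_I=100, Q=5)


@pytest.fixture(scope="session")
def sys_unclustered(table1_spec) -> cn.PopulationSystem:
    return cn.reduce_network(table1_spec)


@pytest.fixture(scope="session")
def fp_unclustered(sys_unclustered) -> cn.FixedPoint:
    """Finite-N mean-field fixed point of the unclustered reference system."""
    return cn.homogeneous_fixed_point(sys_unclustered)


@pytest.fixture(scope="session")
def sim_unclustered(table1_spec) -> cn.SimulationResult:
    """One long unclustered trial at reference parameters (shared across tests)."""
    mat = cn.build_matrix(table1_spec, seed=101)
    return cn.simulate(mat, config=cn.SimulationConfig(duration_ms=2000.0,
                                                       seed=11))


@pytest.fixture(scope="session")
def sim_ei_clustered(table1_spec) -> cn.SimulationResult:
    """EI-clustered trial in the winnerless regime (J_E+=4, R_J=3/4)."""
    spec = table1_spec.replace(clustering_mode="EI_weights", J_Eplus=4.0,
                               R_J=0.75)
    mat = cn.build_matrix(spec, seed=202)
    return cn.simulate(mat, config=cn.SimulationConfig(duration_ms=1000.0,
                                                       seed=22))


def grouped_rates(result, include_inhibitory=False, bin_ms=10.0):
    return cn.cluster_rates(
        result, result.assignment(include_inhibitory=include_inhibitory),
        bin_ms=bin_ms)
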