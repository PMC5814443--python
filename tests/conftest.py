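import numpy as np
import pytest

from oribosim.model import (
    CellModel,
    CircuitGene,
    HostParameters,
    OPoolSpec,
    solve_steady_state,
)


@pytest.fixture(scope="session")
def base_model():
    return CellModel()


@pytest.fixture(scope="session")
def base_ss(base_model):
    ss = solve_steady_state(base_model)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def pool_model():
    m = CellModel()
    m.add_pool(OPoolSpec("o1", omega_rho=500.0))
    return m


@pytest.fixture(scope="session")
def pool_ss(pool_model):
    ss = solve_steady_state(pool_model)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def reporter_hh_model():
    m = CellModel()
    m.add_pool(OPoolSpec("o1", omega_rho=500.0))
    m.add_gene(CircuitGene("RFP", omega=1.0, pool="host"))
    m.add_gene(CircuitGene("GFP", omega=100.0, pool="host"))
    return m


@pytest.fixture
def small_omega_grid():
    return np.logspace(0, 3, 5)
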