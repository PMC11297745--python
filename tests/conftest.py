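import numpy as np
import pytest

from rhizoseit import (
    DipolePoolRules,
    ErrorModel,
    RhizotronGeometry,
    build_mesh,
    enumerate_candidates,
)
from rhizoseit.design import make_design_state, optimize_scheme


@pytest.fixture(scope="session")
def geometry():
    return RhizotronGeometry()


@pytest.fixture(scope="session")
def coarse_mesh(geometry):
    """Coarse rhizotron mesh for FEM/inversion tests (~1-2k cells)."""
    return build_mesh(geometry, base_cell=0.04, refinement_level=0.4)


@pytest.fixture(scope="session")
def design_mesh(geometry):
    return build_mesh(geometry, base_cell=0.045, refinement_level=0.5)


@pytest.fixture(scope="session")
def water_resistivity():
    return 1.0 / 105.1e-4


@pytest.fixture(scope="session")
def design_state(design_mesh, geometry):
    pool = enumerate_candidates(geometry.n_electrodes, DipolePoolRules(skips=(1, 2, 3, 5, 8, 13, 21)))
    return make_design_state(design_mesh, geometry, pool)


@pytest.fixture(scope="session")
def small_scheme(design_state):
    """A modest optimized scheme (200 configurations) shared across tests."""
    state = design_state
    state.selected = []
    state.objective_log = []
    return optimize_scheme(state, target_size=200, dipole_budget=40, batch_size=20)


@pytest.fixture(scope="session")
def synthetic_error_model():
    return ErrorModel(a=0.01, b=0.001, c=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
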