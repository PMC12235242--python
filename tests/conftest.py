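import numpy as np
import pytest

from chromsol.benchmark import TruthSpec, make_programs
from chromsol.dgfem import build_mesh
from chromsol.rhs import ColumnModel
from chromsol.solver import SolverConfig


@pytest.fixture(scope="session")
def truth():
    """Default noiseless benchmark specification."""
    return TruthSpec(noise_rel=0.0, seed=0)


@pytest.fixture(scope="session")
def experiments(truth):
    return make_programs(truth)


@pytest.fixture(scope="session")
def coarse_mesh(truth):
    """Reduced-resolution mesh used by the fast integration tests."""
    return build_mesh(4, 2, truth.column.length)


@pytest.fixture(scope="session")
def default_mesh(truth):
    return build_mesh(7, 3, truth.column.length)


@pytest.fixture(scope="session")
def coarse_solver():
    return SolverConfig(step_fraction=0.01)


@pytest.fixture()
def model(truth, experiments, coarse_mesh):
    """Column model of the first training experiment on the coarse mesh."""
    return ColumnModel(truth.column, truth.components,
                       experiments[0].program, coarse_mesh)


@pytest.fixture()
def generic_state(model):
    """A physically plausible but non-trivial state (loaded column mid-
    gradient): random positive concentrations, partially loaded surface."""
    rng = np.random.default_rng(42)
    state = model.initial_state()
    state[:, model.i_cm] = rng.uniform(35.0, 90.0, model.n_nodes)
    state[:, model.c_slice] = rng.uniform(0.0, 0.8, (model.n_nodes, model.n_comp))
    state[:, model.q_slice] = rng.uniform(0.0, 30.0, (model.n_nodes, model.n_comp))
    state[:, model.i_qm] = (model.ligand
                            - state[:, model.q_slice] @ model.nu)
    return state
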