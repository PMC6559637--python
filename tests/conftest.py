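import numpy as np
import pytest

from retoxsim import (
    AxiGrid,
    ModelParams,
    SolverSettings,
    build_generic_domains,
    solve_steady_state,
)
from retoxsim.synthetic_cohort import CohortConfig


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def settings():
    return SolverSettings()


@pytest.fixture(scope="session")
def generic_field(params, settings):
    """Druse-free laminar solve at 1 μm spacing, shared across tests."""
    grid = AxiGrid(n_r=300, n_z=125, spacing=1.0)
    return solve_steady_state(build_generic_domains(params, grid), params, settings)


@pytest.fixture(scope="session")
def small_cohort_config():
    """A compact synthetic-eye configuration for fast pipeline tests."""
    return CohortConfig(
        seed=7,
        extent_um=3000.0,
        spacing_um=50.0,
        pit_radius=200.0,
        pit_depth=15.0,
        druse_count_mean=5.0,
        druse_diameter_median=200.0,
        misreg_dx=100.0,
        misreg_dy=-50.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
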