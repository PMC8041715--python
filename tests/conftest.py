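import numpy as np
import pytest

from gliomapal import (
    FiberDistributionParams,
    Grid2D,
    MacroParams,
    build_tissue,
    nondimensional_fields,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210412)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse [0, 1000] um grid for fast tissue builds."""
    return Grid2D.square(1000.0, 41)


@pytest.fixture(scope="session")
def iso_tissue(small_grid):
    """Isotropic undirected tissue (uniform fiber distribution)."""
    return build_tissue(small_grid, FiberDistributionParams(delta=1.0))


@pytest.fixture(scope="session")
def aniso_tissue(small_grid):
    """Anisotropic undirected tissue (two crossing bundles)."""
    return build_tissue(small_grid, FiberDistributionParams(delta=0.2, kappa=3.0))


@pytest.fixture(scope="session")
def aniso_fields(aniso_tissue):
    return nondimensional_fields(aniso_tissue, Ds=5e-8, x_scale_mm=0.045, t_scale_s=4e4)


@pytest.fixture()
def experiment_params():
    return MacroParams(alpha=0.01, mu0=0.0926)
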