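import numpy as np
import pytest

from pdeocp.grids import build_grid_1d, build_grid_2d
from pdeocp.models import ChemotaxisParams, ChemotaxisSystem, FHNParams


@pytest.fixture(scope="session")
def grid41():
    return build_grid_1d(1.0, 41)


@pytest.fixture(scope="session")
def chemo_params():
    return ChemotaxisParams()


@pytest.fixture(scope="session")
def chemo_system(chemo_params, grid41):
    return ChemotaxisSystem(chemo_params, grid41, order=4)


@pytest.fixture(scope="session")
def chemo_system_conservative(chemo_params, grid41):
    return ChemotaxisSystem(chemo_params, grid41, order=4, scheme="conservative")


@pytest.fixture(scope="session")
def fhn_params():
    return FHNParams()


@pytest.fixture(scope="session")
def grid2d_small():
    """Coarse 2D grid for fast FHN/POD unit tests (33 nodes per axis is
    about the coarsest resolution that still propagates the pulse)."""
    return build_grid_2d(n1=33, n2=33)
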