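import numpy as np
import pytest

from chemoflow.grid import BCSpec, build_grid
from chemoflow.params import PhysicalParams


@pytest.fixture
def rng():
    return np.random.default_rng(20230817)


@pytest.fixture
def unit_grid():
    """Small unit-square grid for operator tests."""
    return build_grid(0.0, 1.0, 0.0, 1.0, 8, 6)


@pytest.fixture
def model_bc():
    return BCSpec(mode="model")


@pytest.fixture
def unit_params():
    """All dimensionless constants one, r(c) fixed to one."""
    return PhysicalParams(alpha=1, beta=1, gamma=1, zeta=1, Sc=1, eta=1,
                          r_const=1.0)
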