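import numpy as np
import pytest

from bnctbeam import BeamModelParams, generate_beam_spectrum
from bnctbeam.synthetic import CylinderPhantomSpec, DoseKernelParams, default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def beam_params():
    """Default epithermal beam (1 keV peak, strongly epithermal mixture)."""
    return BeamModelParams(name="beam5")


@pytest.fixture(scope="session")
def spectrum(grid, beam_params):
    return generate_beam_spectrum(grid, beam_params, seed=1)


@pytest.fixture(scope="session")
def kernels():
    return DoseKernelParams()


@pytest.fixture()
def phantom():
    return CylinderPhantomSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
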