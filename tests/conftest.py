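import numpy as np
import pytest

from neuroquench.neural_mass import default_1d_spec, default_2d_spec


@pytest.fixture(scope="session")
def spec1d():
    return default_1d_spec()


@pytest.fixture(scope="session")
def spec2d():
    return default_2d_spec()


@pytest.fixture(scope="session")
def coarse_grid():
    """Coarse amplitude grid for fast sweep tests."""
    return np.round(np.arange(-5.0, 5.0001, 0.25), 4)
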