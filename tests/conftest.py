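import numpy as np
import pytest

from ifw import FitConfig, default_scheme


@pytest.fixture(scope="session")
def scheme():
    """Reference 44-volume multi-shell scheme (b=0/200/500/1000, TE 109 ms)."""
    return default_scheme()


@pytest.fixture(scope="session")
def fit_config():
    return FitConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def gm_tensor():
    """Anisotropic tissue tensor with eigenvalues (1.5, 0.4, 0.4)e-3 mm^2/s."""
    return np.diag([1.5e-3, 0.4e-3, 0.4e-3])
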