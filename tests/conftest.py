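import numpy as np
import pytest

from helixmi import ModelParameters, derive_coefficients


@pytest.fixture(scope="session")
def fig2_params():
    """Reference growth-rate parameter set (package defaults)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def fig1_params():
    """Dispersion-figure parameter set."""
    return ModelParameters(m=300.0, I=300.0, a=4.41, chi=1.2, D=0.05,
                           V=0.005, k=0.04, r=0.3)


@pytest.fixture(scope="session")
def fig2_coeffs(fig2_params):
    return derive_coefficients(fig2_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
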