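import numpy as np
import pytest

from lookdyn import ModelParams, simulate_individual


@pytest.fixture
def params():
    """Default parameters: the strong-target-boost regime."""
    return ModelParams()


@pytest.fixture
def weak_params():
    """Uniform weak boosts (the younger-infant regime)."""
    return ModelParams(lam=(1.1, 1.1, 1.1))


@pytest.fixture
def neutral_params():
    """State-independent dynamics: no boost, no refixation bias, gamma=0."""
    return ModelParams(nu=1.0, rho=0.0, lam=(1.0, 1.0, 1.0), gamma=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def session_32():
    """One simulated individual: 32 five-second trials at default params."""
    return simulate_individual(ModelParams(), 32, seed=11)
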