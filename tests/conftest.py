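import numpy as np
import pytest

from dmftnet import (
    AdaptationParams,
    SolverConfig,
    make_adaptation_model,
)


@pytest.fixture(scope="session")
def resonant_params():
    """Strong, slow adaptation: the resonant (Hopf) regime."""
    return AdaptationParams(gamma=0.25, beta=1.0)


@pytest.fixture(scope="session")
def nonresonant_params():
    """Weak, fast adaptation: the saddle-node regime."""
    return AdaptationParams(gamma=1.0, beta=0.1)


@pytest.fixture(scope="session")
def resonant_model(resonant_params):
    return make_adaptation_model(resonant_params)


@pytest.fixture(scope="session")
def nonresonant_model(nonresonant_params):
    return make_adaptation_model(nonresonant_params)


@pytest.fixture(scope="session")
def coarse_config():
    """Coarse, fast solver grid for unit tests."""
    return SolverConfig(freq_step=0.002, max_freq=1.0, seed=0)


@pytest.fixture(scope="session")
def exp_autocorr():
    """Exponential autocorrelation with unit variance on a short grid."""
    from dmftnet import Autocorr

    dt = 0.05
    lags = dt * np.arange(257)
    return Autocorr(lag_step=dt, values=np.exp(-lags))
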