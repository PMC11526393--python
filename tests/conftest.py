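import numpy as np
import pytest

from lvforest import ModelSpec, simulate_responses
from lvforest.simulate import sim1_parameters


@pytest.fixture(scope="session")
def spec57():
    """The five-item, seven-category one-factor model used throughout."""
    return ModelSpec.ordinal(5, 7)


@pytest.fixture(scope="session")
def params_r1():
    """Generating parameters of the first heterogeneous subgroup."""
    return sim1_parameters(0)


@pytest.fixture(scope="session")
def small_sample(spec57, params_r1):
    """One modest model-compliant sample (n=500) with its latent draws."""
    rng = np.random.default_rng(2024)
    eta = rng.normal(
        params_r1.factor_mean, np.sqrt(params_r1.factor_variance), 500
    )
    y = simulate_responses(spec57, params_r1, eta, rng)
    return y, eta
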