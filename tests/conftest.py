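import numpy as np
import pytest

from inflamsim import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def params():
    """Baseline parameter set on a small grid, for fast agent-level tests."""
    return ModelParams(grid_shape=(20, 20), r=3.0)


@pytest.fixture
def quiet_params(params):
    """All event probabilities zero: nothing stochastic ever fires."""
    return params.replace(p_nr=0.0, p_nc=0.0, p_mr=0.0, p_mg=0.0,
                          p_ml=0.0, p_ma=0.0)
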