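import numpy as np
import pytest

from olfec.environment import EnvironmentSpec, StimulusSampler
from olfec.encoding import EncodingParams, make_canonical_expression
from olfec.optimize import init_sensing


@pytest.fixture(scope="session")
def small_env() -> EnvironmentSpec:
    """Desk-scale environment: 200 odorants, 16 sources."""
    return EnvironmentSpec.default(n_odorants=200, n_blocks=16,
                                   conc_log_sd=2.0, seed=11)


@pytest.fixture(scope="session")
def small_batch(small_env):
    return StimulusSampler(small_env).draw(512)


@pytest.fixture(scope="session")
def small_sensing(small_batch):
    """Scaled log-normal sensing matrix for 10 receptors."""
    return init_sensing(10, 200, "scaledLogNormal", small_batch, seed=3)


@pytest.fixture(scope="session")
def encoding_params():
    return EncodingParams()


@pytest.fixture(scope="session")
def canonical_e_small():
    return make_canonical_expression(10, 30)
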