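import numpy as np
import pytest

from boldcbf.core import AcquisitionParams
from boldcbf.synth import uniform_truth

MATRIX = (6, 6, 4)


@pytest.fixture
def acq() -> AcquisitionParams:
    """Scaled-down test acquisition: 6x6x4 grid, the protocol's 90 volumes."""
    return AcquisitionParams(matrix=MATRIX, n_volumes=90)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def truth():
    return uniform_truth(MATRIX, coupling=0.8, lag=-1.05, noise_sd=0.0)
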