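import numpy as np
import pytest

from covnet.simulate import (
    block_partial_corr,
    make_test_atlas,
    precision_from_pcorr,
)


@pytest.fixture(scope="session")
def atlas():
    return make_test_atlas()


@pytest.fixture(scope="session")
def base_precision():
    """Feasible 19-node block precision (within 0.12, between 0.02)."""
    return precision_from_pcorr(block_partial_corr(0.12, 0.02))


@pytest.fixture(scope="session")
def base_covariance(base_precision):
    return np.linalg.inv(base_precision)
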