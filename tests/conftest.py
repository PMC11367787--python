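import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(params=[0.05, 0.1, 0.2, 0.3, 0.45])
def theta(request):
    """Representative recombination fractions across the open interval."""
    return request.param
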