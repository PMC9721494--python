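import numpy as np
import pytest

from sociality import CobbDouglasUtility


@pytest.fixture
def cd75():
    return CobbDouglasUtility(alpha=0.75)


@pytest.fixture
def cd25():
    return CobbDouglasUtility(alpha=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(20221121)
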