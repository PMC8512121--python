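import numpy as np
import pytest

from hawkopt.benchmarks import make_builtin


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sphere2():
    return make_builtin("sphere", 2)


@pytest.fixture
def sphere10():
    return make_builtin("sphere", 10)
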