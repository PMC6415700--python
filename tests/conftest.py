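import numpy as np
import pytest

from tcellfate import load_table1, load_table1_extended
from tcellfate.fixtures import random_star_model


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table1_extended():
    return load_table1_extended()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_models():
    """Factory: n random validated star models from a fixed stream."""

    def make(n, regime="mixed", M=None, seed=77):
        stream = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            m = int(stream.integers(1, 6)) if M is None else M
            out.append(random_star_model(stream, M=m, regime=regime))
        return out

    return make
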