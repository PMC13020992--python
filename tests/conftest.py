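import numpy as np
import pytest

from spherenav.atlas import build_atlas
from spherenav.synthetic import default_design


@pytest.fixture(scope="session")
def atlas():
    return build_atlas()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
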