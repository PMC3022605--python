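import math

import numpy as np
import pytest

from sdnetevo import NetworkParams, get_pair


def sig(x: float, h: float) -> float:
    """Independent scalar sigmoid used as an oracle throughout the tests."""
    return 1.0 / (1.0 + math.exp(-h * x))


@pytest.fixture
def net():
    return NetworkParams(h=3.0, k=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def pair_ffminus():
    """f variant with a down-regulation site fixed first, then the A mutant."""
    return get_pair("ff-/aA")


@pytest.fixture
def pair_aA_mminus():
    """A fixed first, then the m variant with a down-regulation site."""
    return get_pair("aA/mm-")
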