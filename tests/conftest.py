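import numpy as np
import pytest

from memdsn.pssm_io import PSSM


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_pssm(rng):
    """A 30 x 20 integer profile with values in the realistic log-odds range."""
    return PSSM(id="toy", scores=rng.integers(-10, 11, size=(30, 20)))


def random_pssm(rng, length):
    return PSSM(id=f"r{length}", scores=rng.integers(-15, 16, size=(length, 20)))
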