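import numpy as np
import pytest

from ejmotif.motif import MotifModel, PositionWeighting, SubstitutionMatrix


@pytest.fixture(scope="session")
def pam250():
    return SubstitutionMatrix()


@pytest.fixture(scope="session")
def default_model():
    return MotifModel()


@pytest.fixture(scope="session")
def w156():
    return PositionWeighting.from_positions((1, 5, 6))


@pytest.fixture(scope="session")
def w145():
    return PositionWeighting.from_positions((1, 4, 5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
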