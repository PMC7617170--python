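import numpy as np
import pytest

from physeg.labels import pgs_labels
from physeg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom32():
    """A 32-cube phantom with its generating labels (seed 7)."""
    return generate_phantom(PhantomSpec(shape=(32, 32, 32), seed=7))


@pytest.fixture(scope="session")
def mpm32(phantom32):
    return phantom32[0]


@pytest.fixture(scope="session")
def pgs32(mpm32):
    return pgs_labels(mpm32)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
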