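import numpy as np
import pytest

from craniomsp.phantom import PhantomSpec, make_phantom
from craniomsp.volume_io import Volume


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 32-cubed symmetric phantom spec used across module tests."""
    return PhantomSpec().scaled((32, 32, 32))


@pytest.fixture(scope="session")
def small_phantom(small_spec) -> Volume:
    return make_phantom(small_spec, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_mask(rng, shape, p=0.3) -> Volume:
    return Volume((rng.random(shape) < p).astype(np.uint8))
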