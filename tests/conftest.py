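import numpy as np
import pytest

from uperc3d import PhantomConfig, Volume3D, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom() -> Volume3D:
    return generate_phantom(PhantomConfig(shape=(32, 32, 32), n_tubes=3), seed=7)


@pytest.fixture
def random_volume(rng) -> Volume3D:
    return Volume3D(rng.random((12, 12, 12), dtype=np.float32))
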