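import numpy as np
import pytest

from lmbisnet.synth import SynthConfig, make_dataset
from lmbisnet.types import FundusSample


@pytest.fixture(scope="session")
def tiny_dataset():
    """Four small synthetic fundus samples (64 px), shared across tests."""
    return make_dataset(4, SynthConfig(side=64, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_sample(rng):
    img = rng.random((16, 16, 3))
    mask = (rng.random((16, 16)) > 0.7).astype(np.uint8)
    fov = np.ones((16, 16), dtype=np.uint8)
    return FundusSample(id="rnd", image=img, vessel_mask=mask, fov_mask=fov)
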