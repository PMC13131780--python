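import numpy as np
import pytest

from swinpick.io import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """Small float volume with distinguishable values and non-unit metadata."""
    data = rng.normal(size=(10, 12, 14)).astype(np.float32)
    return Volume(data, voxel_size=(1.5, 2.0, 2.5), origin=(3.0, -4.0, 5.0))


@pytest.fixture
def label_volume(rng):
    data = rng.integers(0, 4, size=(9, 10, 11)).astype(np.int64)
    return Volume(data)
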