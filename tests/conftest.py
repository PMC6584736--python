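import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_volume(rng):
    from tumortopo import VoxelGrid

    return VoxelGrid(rng.random((10, 9, 8)) * 255.0, spacing=(1.2, 1.2, 3.0))
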