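import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from somatomap.ephys import standard_protocol
from somatomap.stacks import BinaryMask


@pytest.fixture(scope="session")
def protocol():
    """The standard ramp-and-hold / vibration / tap characterization."""
    return standard_protocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.4, voxel=(2.0, 1.0, 1.0)):
    """A random non-empty binary mask."""
    while True:
        data = rng.random(shape) < p
        if data.any():
            return BinaryMask(data=data, voxel_size_um=voxel)


@pytest.fixture()
def make_random_mask(rng):
    return lambda shape=(5, 6, 7), p=0.4: random_mask(rng, shape, p)
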