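import numpy as np
import pytest

from fuzzedge import GrayImage, make_disk_phantom


@pytest.fixture(scope="session")
def disk_truth():
    """Noiseless disk phantom (side 64, radius 15) used across modules."""
    return make_disk_phantom(64, (31.5, 31.5), 15.0, inside=200, outside=50)


@pytest.fixture()
def random_gray():
    def _make(side=16, seed=0, value_range=255.0):
        rng = np.random.default_rng(seed)
        return GrayImage(rng.integers(0, int(value_range) + 1, (side, side)).astype(float), value_range)

    return _make
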