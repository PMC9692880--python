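import numpy as np
import pytest

from tsdbox.boxes import Box


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, center_range=(0.0, 512.0), side_range=(1.0, 64.0)) -> Box:
    cx, cy = rng.uniform(*center_range, size=2)
    w, h = rng.uniform(*side_range, size=2)
    return Box.from_center(cx, cy, w, h)


def random_pair(rng, center_range=(0.0, 512.0), side_range=(1.0, 64.0)):
    return (
        random_box(rng, center_range, side_range),
        random_box(rng, center_range, side_range),
    )


@pytest.fixture
def random_pairs(rng):
    def make(n, center_range=(0.0, 512.0), side_range=(1.0, 64.0)):
        return [random_pair(rng, center_range, side_range) for _ in range(n)]

    return make
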