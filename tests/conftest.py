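import numpy as np
import pytest

from fluorosynth.io_formats import LeafLabelImage
from fluorosynth.plantshapes import RosetteSpec, generate_rosette


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_label():
    """A tiny hand-built 3-leaf label image (10x10)."""
    labels = np.zeros((10, 10), dtype=np.int32)
    labels[1:4, 1:4] = 1
    labels[5:9, 2:5] = 2
    labels[2:6, 6:9] = 3
    return LeafLabelImage(labels=labels, source="procedural")


@pytest.fixture
def rosette_label():
    """A deterministic procedural rosette at the working resolution."""
    return generate_rosette(RosetteSpec(n_leaves=8, canvas_size=128, seed=7))


def random_class_mask(rng, shape=(16, 16), p=(0.5, 0.3, 0.2)):
    return rng.choice([0, 1, 2], size=shape, p=p).astype(np.uint8)
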