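import numpy as np
import pytest

from octaquant import vessels
from octaquant.synth_slabs import SlabSimParams, generate_vascular_slab


@pytest.fixture(scope="session")
def default_slab():
    """One default-parameter synthetic retinal slab with ground truth."""
    img, truth = generate_vascular_slab(SlabSimParams(seed=0))
    return img, truth


@pytest.fixture(scope="session")
def default_segmentation(default_slab):
    """Segmentation of the default slab (expensive; shared across tests)."""
    img, _ = default_slab
    return vessels.segment_vessels(img)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
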