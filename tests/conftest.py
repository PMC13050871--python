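import numpy as np
import pytest

from ribbonquant.core import ImageStack
from ribbonquant.synthetic import SynthConfig, make_confocal_stack


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic confocal dataset (moderate noise), shared."""
    cfg = SynthConfig(seed=11)
    stacks, manifest = make_confocal_stack(cfg)
    return cfg, stacks, manifest


@pytest.fixture(scope="session")
def clean_world():
    """Noise-free variant of the default synthetic dataset."""
    cfg = SynthConfig(seed=11, poisson_scale=0.0, read_noise_sd=0.0)
    stacks, manifest = make_confocal_stack(cfg)
    return cfg, stacks, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_stack(arr, voxel=(0.2, 0.08, 0.08)):
    return ImageStack(np.asarray(arr, dtype=float), voxel_size_um=voxel)
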