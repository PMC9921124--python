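"""Shared fixtures: small phantoms and seeded generators."""

import numpy as np
import pytest

from prostseg.augment import TrainingSample
from prostseg.io_preprocess import znormalize
from prostseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_phantom_cfg():
    return PhantomConfig(grid_shape=(32, 32, 8), spacing=(2.4, 2.4, 6.6),
                         radii_range_mm=(14, 24), seed=3)


@pytest.fixture(scope="session")
def desk_sample(desk_phantom_cfg):
    """One 32x32x8 phantom as a z-normalized training sample."""
    s = generate_phantom(desk_phantom_cfg)
    return TrainingSample(image=znormalize(s.image), label=s.mask)


@pytest.fixture(scope="session")
def medium_phantom():
    cfg = PhantomConfig(grid_shape=(64, 64, 16), spacing=(1.2, 1.2, 3.3),
                        radii_range_mm=(14, 24), seed=11)
    return generate_phantom(cfg)
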