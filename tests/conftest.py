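import numpy as np
import pytest

from cortiqct import (MorphometryConfig, PhantomSpec, SegmentationConfig,
                      generate_phantom, segment_vertebra)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()  # 2 mm shell, noiseless, blur-free


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def default_segmentation(default_phantom):
    volume, _ = default_phantom
    return segment_vertebra(volume, SegmentationConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def morph_config():
    return MorphometryConfig()
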