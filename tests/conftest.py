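import numpy as np
import pytest

from cvit3d.model import ModelConfig, CVit3D


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature architecture for fast CPU tests: 8x16x16 input, 32 tokens."""
    return ModelConfig(
        input_shape=(8, 16, 16),
        stem_channels=4,
        stem_stride=2,
        msfe_channels=(8,),
        msfe_strides=(2,),
        embed_dim=16,
        depth=1,
        num_heads=2,
        mlp_ratio=2.0,
        se_reduction=2,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return CVit3D(tiny_config, seed=7)


@pytest.fixture(scope="session")
def tiny_batch(tiny_config):
    r = np.random.default_rng(11)
    x = r.standard_normal((3, 5, *tiny_config.input_shape)).astype(np.float32)
    return x
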