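import numpy as np
import pytest

from cattlepose import synthetic
from cattlepose.network import ModelConfig, build_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """A very narrow improved-architecture config for fast forward passes."""
    return ModelConfig(width_multiple=0.0625, simam_stages=("P3", "P4", "P5"),
                       neck="efficient_rep_bipan",
                       neck_channels=(16, 8, 16, 32),
                       repblock_depths=(1, 1, 1, 1))


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """20 synthetic scenes at 96 px with labels, shared across tests."""
    out = tmp_path_factory.mktemp("ds")
    return synthetic.generate_dataset(20, seed=42, out_dir=out, image_size=96)
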