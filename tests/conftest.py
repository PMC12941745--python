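import numpy as np
import pytest

from freqsr.config import GeneratorConfig, RunConfig
from freqsr.fixtures import FixtureSpec, make_hr_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def blob_image():
    return make_hr_image(FixtureSpec(kind="blobs", size=(64, 64), seed=7))


@pytest.fixture
def texture_image():
    return make_hr_image(FixtureSpec(kind="texture", size=(64, 64), seed=11))


@pytest.fixture
def tiny_gen_cfg():
    """A small generator config for fast structural tests."""
    cfg = GeneratorConfig(base_channels=8, n_rmb=1, mpms_per_rmb=2, n_cam=1,
                          se_reduction=4, large_kernel=9, scale=2)
    cfg.k1 = 2
    cfg.k2 = 4
    return cfg


@pytest.fixture
def tiny_run_cfg(tiny_gen_cfg):
    cfg = RunConfig(scale=2, seed=5)
    cfg.generator = tiny_gen_cfg
    cfg.discriminator.base_channels = 8
    cfg.discriminator.n_stages = 2
    cfg.train.batch_size = 2
    cfg.train.iterations = 3
    cfg.train.crop = 32
    cfg.train.augment = ("rot90", "hflip")
    return cfg.validate()
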