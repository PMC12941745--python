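import numpy as np
import pytest

from freqsr.config import BlurKernel
from freqsr.degradation import NoisePool
from freqsr.fixtures import FixtureSpec, make_hr_image
from freqsr.losses import make_feature_extractor
from freqsr.training import (
    augment,
    init_state,
    load_checkpoint,
    make_training_pair,
    save_checkpoint,
    train,
    train_step,
)


class AlwaysFire:
    """rng stub: every probability-1/2 draw fires; rotation k and choices fixed."""

    def __init__(self, k=1, choice=0):
        self.k, self.choice, self._calls = k, choice, 0

    def integers(self, *args, **kwargs):
        hi = args[1] if len(args) > 1 else args[0]
        if hi == 2:
            return 1  # fire the coin flip
        if hi == 4:
            return self.k
        return self.choice


@pytest.fixture
def small_images():
    return [make_hr_image(FixtureSpec(kind=k, size=(32, 32), seed=i))
            for i, k in enumerate(["texture", "blobs", "checkerboard", "gradient"])]


@pytest.fixture
def tiny_pool(rng):
    patches = [0.01 * rng.standard_normal((3, 8, 8)).astype(np.float32) for _ in range(4)]
    patches = [p - p.mean(axis=(1, 2), keepdims=True) for p in patches]
    return NoisePool(patches=patches)


class TestAugment:
    def test_disabled_is_identity(self, blob_image, rng):
        assert np.array_equal(augment(blob_image, rng, enabled=()), blob_image)

    def test_forced_hflip_is_involution(self, blob_image):
        once = augment(blob_image, AlwaysFire(), enabled=("hflip",))
        twice = augment(once, AlwaysFire(), enabled=("hflip",))
        assert not np.array_equal(once, blob_image)
        assert np.array_equal(twice, blob_image)

    def test_rot90_and_hflip_preserve_pixel_multiset(self, blob_image):
        out = augment(blob_image, AlwaysFire(k=3), enabled=("rot90", "hflip"))
        assert np.array_equal(np.sort(out.ravel()), np.sort(blob_image.ravel()))

    def test_scale_respects_min_size(self, blob_image):
        out = augment(blob_image, AlwaysFire(choice=0), enabled=("scale",), min_size=64)
        assert out.shape == blob_image.shape  # 0.7*64 < 64 -> clamped
        shrunk = augment(blob_image, AlwaysFire(choice=0), enabled=("scale",), min_size=16)
        assert shrunk.shape == (3, 45, 45)  # round(0.7 * 64)
        assert shrunk.min() >= 0 and shrunk.max() <= 1


class TestMakeTrainingPair:
    def test_shapes(self, tiny_run_cfg, blob_image, rng):
        lr, hr = make_training_pair(blob_image, tiny_run_cfg, None, rng)
        assert hr.shape == (3, 32, 32)
        assert lr.shape == (3, 16, 16)

    def test_deterministic_under_fixed_rng(self, tiny_run_cfg, blob_image):
        a = make_training_pair(blob_image, tiny_run_cfg, None, np.random.default_rng(5))
        b = make_training_pair(blob_image, tiny_run_cfg, None, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_identity_degradation_scale_one(self, tiny_run_cfg, blob_image, rng):
        cfg = tiny_run_cfg
        cfg.degradation.scale = 1
        cfg.degradation.kernel = BlurKernel(size=1)
        cfg.degradation.noise_mode = "none"
        lr, hr = make_training_pair(blob_image, cfg, None, rng)
        assert np.allclose(lr, hr, atol=1e-6)

    def test_too_small_hr_rejected(self, tiny_run_cfg, rng):
        small = np.zeros((3, 16, 16), np.float32)
        with pytest.raises(ValueError, match="crop"):
            make_training_pair(small, tiny_run_cfg, None, rng)


class TestTrainStep:
    def test_counters_and_history(self, tiny_run_cfg, small_images, tiny_pool):
        cfg = tiny_run_cfg
        cfg.train.d_steps_per_g = 2
        state = init_state(cfg)
        fx = make_feature_extractor(cfg.loss, cfg.seed)
        batch = [make_training_pair(im, cfg, tiny_pool, state.rng) for im in small_images[:2]]
        state, bundle, d_loss = train_step(state, batch, fx)
        assert state.iteration == 1
        assert len(state.loss_history) == 1
        assert state.d_opt.t == 2  # two discriminator updates per generator update
        assert state.g_opt.t == 1
        assert bundle.per == pytest.approx(
            bundle.spa + cfg.loss.lambda1 * bundle.col + cfg.loss.lambda2 * bundle.adv,
            rel=1e-5,
        )

    def test_smoke_run_writes_loadable_checkpoint(self, tiny_run_cfg, small_images, tmp_path):
        cfg = tiny_run_cfg
        cfg.train.iterations = 4
        cfg.train.checkpoint_every = 2
        cfg.degradation.noise_mode = "gaussian"
        state = train(cfg, small_images, out_dir=tmp_path)
        assert state.iteration == 4
        assert (tmp_path / "checkpoint.npz").exists()
        assert (tmp_path / "losses.csv").exists()
        loaded = load_checkpoint(tmp_path / "checkpoint.npz", cfg)
        assert loaded.iteration == 4
        for (ka, pa), (kb, pb) in zip(
            state.generator.named_parameters(), loaded.generator.named_parameters()
        ):
            assert ka == kb and np.array_equal(pa.data, pb.data)

    def test_resume_reproduces_uninterrupted_losses(self, tiny_run_cfg, small_images, tmp_path):
        cfg = tiny_run_cfg
        cfg.degradation.noise_mode = "gaussian"
        cfg.train.iterations = 2
        cfg.train.checkpoint_every = 100
        state = train(cfg, small_images, out_dir=tmp_path)
        save_checkpoint(state, tmp_path / "ckpt2.npz")

        cfg.train.iterations = 4
        full = train(cfg, small_images, state=state)
        resumed = train(cfg, small_images,
                        state=load_checkpoint(tmp_path / "ckpt2.npz", cfg))
        a = [h["per"] for h in full.loss_history[2:]]
        b = [h["per"] for h in resumed.loss_history[2:]]
        assert a == b
        d_a = [h["d_loss"] for h in full.loss_history[2:]]
        d_b = [h["d_loss"] for h in resumed.loss_history[2:]]
        assert d_a == d_b

    def test_two_identical_runs_identical_losses(self, tiny_run_cfg, small_images):
        cfg = tiny_run_cfg
        cfg.degradation.noise_mode = "gaussian"
        runs = []
        for _ in range(2):
            state = train(cfg, small_images)
            runs.append([h["per"] for h in state.loss_history])
        assert runs[0] == runs[1]

    def test_empty_dataset_rejected(self, tiny_run_cfg):
        with pytest.raises(ValueError):
            train(tiny_run_cfg, [])
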