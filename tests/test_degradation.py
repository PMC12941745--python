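import numpy as np
import pytest

from freqsr.config import BlurKernel, DegradationConfig, PatchWindow
from freqsr.degradation import (
    EmptyPoolError,
    NoisePool,
    anisotropic_gaussian_kernel,
    collect_noise_pool,
    degrade,
    is_smooth_patch,
    sample_noise,
)


def oracle_smooth(patch, window):
    """Independent brute-force evaluation of the smooth-patch rule."""
    d, dl, sl = window.d, window.dl, window.sl
    flat = patch.reshape(-1).astype(np.float64)
    mp, vp = flat.mean(), flat.var()
    for r in range(0, d - dl + 1, sl):
        for c in range(0, d - dl + 1, sl):
            q = patch[:, r:r + dl, c:c + dl].reshape(-1).astype(np.float64)
            mq, vq = q.mean(), q.var()
            ok_m = abs(mq - mp) <= window.alpha * mp if mp > 0 else abs(mq - mp) <= 1e-12
            ok_v = abs(vq - vp) <= window.beta * vp if vp > 0 else abs(vq - vp) <= 1e-12
            if not (ok_m and ok_v):
                return False
    return True


class TestSmoothPatch:
    def test_constant_patch_is_smooth(self):
        w = PatchWindow()
        assert is_smooth_patch(np.full((3, 16, 16), 0.5, np.float32), w)

    def test_two_block_patch_is_not_smooth(self):
        # halves of 0 and 1: an 8x8 local window covers a single half, so its
        # mean (0 or 1) differs from the global mean 0.5 by far more than 10%
        w = PatchWindow(d=16, dl=8, sl=8, alpha=0.1, beta=0.1)
        patch = np.zeros((3, 16, 16), np.float32)
        patch[:, :, 8:] = 1.0
        assert not is_smooth_patch(patch, w)

    def test_agrees_with_bruteforce_on_random_patches(self, rng):
        w = PatchWindow(d=16, dl=8, sg=8, sl=4, alpha=0.1, beta=0.1)
        agree = 0
        for _ in range(200):
            base = rng.uniform(0.2, 0.8)
            amp = rng.uniform(0.0, 0.3)
            patch = np.clip(base + amp * rng.standard_normal((3, 16, 16)), 0, 1).astype(np.float32)
            if is_smooth_patch(patch, w) == oracle_smooth(patch, w):
                agree += 1
        assert agree == 200

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            is_smooth_patch(np.zeros((3, 8, 8)), PatchWindow(d=8, dl=8))
        with pytest.raises(ValueError):
            is_smooth_patch(np.zeros((3, 10, 10)), PatchWindow(d=16, dl=8))


class TestNoisePool:
    def test_constant_image_gives_zero_patches(self):
        w = PatchWindow()
        pool = collect_noise_pool([np.full((3, 32, 32), 0.4, np.float32)], w)
        assert len(pool) > 0
        for p in pool.patches:
            assert np.allclose(p, 0.0, atol=1e-6)

    def test_patches_are_zero_mean_per_channel(self, rng):
        w = PatchWindow(alpha=0.9, beta=0.9)
        img = np.clip(0.5 + 0.05 * rng.standard_normal((3, 48, 48)), 0, 1).astype(np.float32)
        pool = collect_noise_pool([img], w)
        assert len(pool) > 0
        for p in pool.patches:
            assert np.abs(p.mean(axis=(1, 2))).max() <= 1e-6

    def test_pool_size_matches_window_enumeration(self, rng):
        # left half flat(ish), right half strongly textured: only left windows qualify
        w = PatchWindow(d=16, dl=8, sg=16, sl=8, alpha=0.5, beta=0.5)
        img = np.empty((3, 32, 64), np.float32)
        img[:, :, :32] = 0.5 + 0.01 * rng.standard_normal((3, 32, 32))
        img[:, :, 32:] = rng.uniform(0, 1, (3, 32, 32))
        pool = collect_noise_pool([img], w)
        expected = sum(
            oracle_smooth(img[:, r:r + 16, c:c + 16], w)
            for r in range(0, 32 - 16 + 1, 16)
            for c in range(0, 64 - 16 + 1, 16)
        )
        assert len(pool) == expected > 0

    def test_pool_grows_with_looser_tolerances(self, rng):
        img = np.clip(0.5 + 0.1 * rng.standard_normal((3, 48, 48)), 0, 1).astype(np.float32)
        sizes = [
            len(collect_noise_pool([img], PatchWindow(alpha=a, beta=b)))
            for a, b in [(0.01, 0.01), (0.1, 0.1), (0.9, 0.9)]
        ]
        assert sizes == sorted(sizes)
        assert sizes[-1] == 5 * 5  # every window smooth as alpha, beta -> 1

    def test_save_load_round_trip(self, rng, tmp_path):
        w = PatchWindow(alpha=0.9, beta=0.9)
        img = np.clip(0.5 + 0.05 * rng.standard_normal((3, 32, 32)), 0, 1).astype(np.float32)
        pool = collect_noise_pool([img], w)
        pool.save(tmp_path / "pool.npz")
        back = NoisePool.load(tmp_path / "pool.npz")
        assert len(back) == len(pool)
        for a, b in zip(pool.patches, back.patches):
            assert np.array_equal(a, b)
        assert back.sources == pool.sources


class TestSampleNoise:
    def _pool_of(self, patches):
        return NoisePool(patches=[p.astype(np.float32) for p in patches])

    def test_zero_pool_gives_zero_noise(self, rng):
        pool = self._pool_of([np.zeros((3, 8, 8))] * 3)
        assert np.array_equal(sample_noise(pool, rng, (20, 20)), np.zeros((3, 20, 20)))

    def test_single_tile_is_flip_of_member(self, rng):
        patch = rng.standard_normal((3, 8, 8)).astype(np.float32)
        pool = self._pool_of([patch])
        out = sample_noise(pool, rng, (8, 8))
        variants = [patch, patch[:, :, ::-1], patch[:, ::-1, :], patch[:, ::-1, ::-1]]
        assert any(np.array_equal(out, v) for v in variants)

    def test_deterministic_given_rng_seed(self):
        patches = [np.random.default_rng(i).standard_normal((3, 8, 8)) for i in range(4)]
        pool = self._pool_of(patches)
        a = sample_noise(pool, np.random.default_rng(42), (24, 20))
        b = sample_noise(pool, np.random.default_rng(42), (24, 20))
        assert np.array_equal(a, b)

    def test_empty_pool_error_mentions_fallback(self, rng):
        with pytest.raises(EmptyPoolError, match="gaussian"):
            sample_noise(NoisePool(), rng, (16, 16))


class TestBlurKernel:
    def test_isotropic_invariant_under_rotation(self):
        k0 = anisotropic_gaussian_kernel(BlurKernel(11, 1.5, 1.5, 0.0))
        k1 = anisotropic_gaussian_kernel(BlurKernel(11, 1.5, 1.5, 0.77))
        assert np.allclose(k0, k1, atol=1e-12)

    @pytest.mark.parametrize("kern", [
        BlurKernel(11, 1.5, 1.5, 0.0),
        BlurKernel(15, 3.0, 0.5, 0.3),
        BlurKernel(7, 0.8, 0.4, 2.0),
    ])
    def test_normalized_and_nonnegative(self, kern):
        k = anisotropic_gaussian_kernel(kern)
        assert abs(k.sum() - 1.0) <= 1e-12
        assert (k >= 0).all()

    def test_major_axis_carries_mass(self):
        k = anisotropic_gaussian_kernel(BlurKernel(21, 4.0, 0.3, 0.0))
        centre_row = k[(21 - 1) // 2, :]
        assert centre_row.sum() > 0.9

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            anisotropic_gaussian_kernel(BlurKernel(11, -1.0, 1.0, 0.0))


class TestDegrade:
    def test_identity(self, texture_image):
        cfg = DegradationConfig(kernel=BlurKernel(size=1), scale=1, noise_mode="none")
        out = degrade(texture_image, cfg)
        assert np.allclose(out, texture_image, atol=1e-6)

    def test_constant_stays_constant(self):
        cfg = DegradationConfig(kernel=BlurKernel(9, 2.0, 1.0, 0.5), scale=2, noise_mode="none")
        out = degrade(np.full((3, 32, 32), 0.3, np.float32), cfg)
        assert out == pytest.approx(0.3, abs=1e-6)

    def test_matches_blur_then_decimate_oracle(self, blob_image):
        cfg = DegradationConfig(kernel=BlurKernel(7, 1.5, 1.0, 0.4), scale=2, noise_mode="none")
        out = degrade(blob_image, cfg)
        kern = anisotropic_gaussian_kernel(cfg.kernel)
        # direct dense correlation with symmetric padding, then take every 2nd pixel
        pad = 3
        expected = np.empty((3, 32, 32))
        for ch in range(3):
            padded = np.pad(blob_image[ch].astype(np.float64), pad, mode="symmetric")
            blurred = np.zeros((64, 64))
            for u in range(7):
                for v in range(7):
                    blurred += kern[u, v] * padded[u:u + 64, v:v + 64]
            expected[ch] = blurred[::2, ::2]
        assert np.allclose(out, np.clip(expected, 0, 1), atol=1e-5)

    def test_indivisible_size_rejected(self):
        cfg = DegradationConfig(scale=4)
        with pytest.raises(ValueError):
            degrade(np.zeros((3, 30, 32), np.float32), cfg)

    def test_pool_mode_requires_pool(self, blob_image, rng):
        cfg = DegradationConfig(noise_mode="pool")
        with pytest.raises(EmptyPoolError):
            degrade(blob_image, cfg, pool=None, rng=rng)

    def test_output_in_unit_range_with_noise(self, blob_image, rng):
        cfg = DegradationConfig(noise_mode="gaussian", noise_sigma=0.2)
        out = degrade(blob_image, cfg, rng=rng)
        assert out.min() >= 0.0 and out.max() <= 1.0
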