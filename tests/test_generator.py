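import numpy as np
import pytest

from freqsr.generator import (
    CAM,
    MPMS,
    RMB,
    Generator,
    UpsampleStage,
    count_parameters,
    generator_forward,
    k_sparse_channel_attention,
)
from freqsr.config import GeneratorConfig
from freqsr.nn import Conv2d, Tensor


def zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestMPMS:
    def test_zero_input_zero_bias_gives_zero(self, rng, tiny_gen_cfg):
        blk = MPMS(rng, 8, tiny_gen_cfg)
        out = blk(Tensor(np.zeros((2, 8, 12, 12), np.float32)))
        assert np.allclose(out.data, 0.0, atol=1e-7)

    @pytest.mark.parametrize("hw", [(16, 16), (17, 17), (9, 14)])
    def test_spatial_shape_preserved(self, rng, tiny_gen_cfg, hw):
        blk = MPMS(rng, 8, tiny_gen_cfg)
        x = Tensor(rng.standard_normal((1, 8, *hw)).astype(np.float32))
        assert blk(x).shape == x.shape

    def test_output_is_product_of_exposed_branches(self, rng, tiny_gen_cfg):
        blk = MPMS(rng, 8, tiny_gen_cfg)
        x = Tensor(rng.standard_normal((1, 8, 10, 10)).astype(np.float32))
        f_mul, f_hie = blk.branches(x)
        assert np.allclose(blk(x).data, f_mul.data * f_hie.data, atol=1e-6)

    def test_channel_mismatch_rejected(self, rng, tiny_gen_cfg):
        blk = MPMS(rng, 8, tiny_gen_cfg)
        with pytest.raises(ValueError, match="channels"):
            blk(Tensor(np.zeros((1, 4, 8, 8), np.float32)))


class TestRMB:
    def test_zero_parameters_reduce_to_identity(self, rng, tiny_gen_cfg):
        blk = RMB(rng, 8, tiny_gen_cfg)
        zero_params(blk)
        x = Tensor(rng.uniform(-1, 1, (1, 8, 9, 9)).astype(np.float32))
        assert np.allclose(blk(x).data, x.data, atol=1e-7)

    def test_matches_hand_chained_composition(self, rng):
        cfg = GeneratorConfig(base_channels=8, mpms_per_rmb=3, se_reduction=4, large_kernel=9)
        blk = RMB(rng, 8, cfg)
        x = Tensor(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
        y1 = blk.blocks[0](x)
        y2 = blk.blocks[1](y1)
        y3 = blk.blocks[2](y2)
        expected = x.data + y1.data + y3.data
        assert np.allclose(blk(x).data, expected, atol=1e-6)


class TestKSparseAttention:
    def test_probability_vector(self, rng):
        x = Tensor(rng.standard_normal((3, 16, 6, 6)).astype(np.float32))
        w = k_sparse_channel_attention(x, 4, 8)
        assert w.shape == (3, 16, 1, 1)
        sums = w.data.sum(axis=1).ravel()
        assert np.allclose(sums, 1.0, atol=1e-6)
        assert (w.data >= 0).all()

    def test_topk_matches_sorting_oracle(self, rng):
        for _ in range(50):
            x = rng.standard_normal((1, 12, 5, 5)).astype(np.float32)
            k1, k2 = 3, 6
            w = k_sparse_channel_attention(Tensor(x), k1, k2, 0.1, 0.3)
            s1 = np.abs(x[0]).mean(axis=(1, 2))
            s2 = x[0].var(axis=(1, 2))
            m1 = np.zeros(12)
            m1[np.argsort(-s1, kind="stable")[:k1]] = 1
            m2 = np.zeros(12)
            m2[np.argsort(-s2, kind="stable")[:k2]] = 1
            logits = 0.1 * s1 * m1 + 0.3 * s2 * m2
            expected = np.exp(logits - logits.max())
            expected /= expected.sum()
            assert np.allclose(w.data[0, :, 0, 0], expected, atol=1e-5)

    def test_k_larger_than_channels_rejected(self, rng):
        x = Tensor(rng.standard_normal((1, 4, 3, 3)).astype(np.float32))
        with pytest.raises(ValueError):
            k_sparse_channel_attention(x, 8, 2)

    def test_gradient_flows_through_scores(self, rng):
        x = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32), requires_grad=True)
        w = k_sparse_channel_attention(x, 2, 4)
        (w * w).sum().backward()
        assert x.grad is not None and np.abs(x.grad).sum() > 0


class TestCAM:
    def test_zero_inputs_zero_biases_give_zero(self, rng, tiny_gen_cfg):
        cam = CAM(rng, 8, tiny_gen_cfg)
        z = Tensor(np.zeros((1, 8, 8, 8), np.float32))
        fh, fl = cam(z, z)
        assert np.allclose(fh.data, 0.0, atol=1e-7)
        assert np.allclose(fl.data, 0.0, atol=1e-7)

    @pytest.mark.parametrize("hw", [(8, 8), (13, 13)])
    def test_shapes_preserved(self, rng, tiny_gen_cfg, hw):
        cam = CAM(rng, 8, tiny_gen_cfg)
        fh = Tensor(rng.standard_normal((1, 8, *hw)).astype(np.float32))
        fl = Tensor(rng.standard_normal((1, 8, *hw)).astype(np.float32))
        oh, ol = cam(fh, fl)
        assert oh.shape == fh.shape and ol.shape == fl.shape

    def test_stream_shape_mismatch_rejected(self, rng, tiny_gen_cfg):
        cam = CAM(rng, 8, tiny_gen_cfg)
        with pytest.raises(ValueError):
            cam(Tensor(np.zeros((1, 8, 8, 8), np.float32)),
                Tensor(np.zeros((1, 8, 9, 9), np.float32)))


class TestUpsampleStage:
    def test_doubles_spatial_size(self, rng):
        stage = UpsampleStage(rng, 8)
        x = Tensor(rng.standard_normal((2, 8, 16, 16)).astype(np.float32))
        assert stage(x).shape == (2, 8, 32, 32)

    def test_zero_parameters_reduce_to_bilinear(self, rng):
        stage = UpsampleStage(rng, 4)
        zero_params(stage)
        x = rng.standard_normal((1, 4, 6, 6)).astype(np.float32)
        out = stage(Tensor(x)).data
        expected = _bilinear_oracle(x)
        assert np.allclose(out, expected, atol=1e-6)


def _bilinear_oracle(x):
    """Index-by-index x2 bilinear interpolation, half-pixel centres."""
    b, c, h, w = x.shape
    out = np.zeros((b, c, 2 * h, 2 * w), np.float32)
    for j in range(2 * h):
        src = (j + 0.5) / 2 - 0.5
        j0 = int(np.clip(np.floor(src), 0, h - 1))
        j1 = min(j0 + 1, h - 1)
        fj = max(src - np.floor(src), 0.0) if src >= 0 else 0.0
        for k in range(2 * w):
            src_k = (k + 0.5) / 2 - 0.5
            k0 = int(np.clip(np.floor(src_k), 0, w - 1))
            k1 = min(k0 + 1, w - 1)
            fk = max(src_k - np.floor(src_k), 0.0) if src_k >= 0 else 0.0
            out[:, :, j, k] = (
                (1 - fj) * (1 - fk) * x[:, :, j0, k0]
                + (1 - fj) * fk * x[:, :, j0, k1]
                + fj * (1 - fk) * x[:, :, j1, k0]
                + fj * fk * x[:, :, j1, k1]
            )
    return out


class TestGenerator:
    def test_output_shape_and_range(self, rng, tiny_gen_cfg):
        gen = Generator(rng, tiny_gen_cfg)
        lr = rng.uniform(0, 1, (3, 32, 32)).astype(np.float32)
        sr = generator_forward(lr, gen)
        assert sr.shape == (3, 64, 64)
        assert sr.min() >= 0.0 and sr.max() <= 1.0

    @pytest.mark.parametrize("scale,size", [(2, 16), (2, 24), (4, 16)])
    def test_scale_contract(self, rng, scale, size):
        cfg = GeneratorConfig(base_channels=8, n_rmb=1, mpms_per_rmb=1, n_cam=1,
                              se_reduction=4, large_kernel=9, scale=scale)
        cfg.k1, cfg.k2 = 2, 4
        gen = Generator(rng, cfg)
        lr = rng.uniform(0, 1, (3, size, size)).astype(np.float32)
        assert generator_forward(lr, gen).shape == (3, scale * size, scale * size)

    def test_every_parameter_receives_gradient(self, rng, tiny_gen_cfg):
        gen = Generator(rng, tiny_gen_cfg)
        lr = Tensor(rng.uniform(0.2, 0.8, (2, 3, 16, 16)).astype(np.float32))
        out = gen(lr)
        (out * out).sum().backward()
        missing = [n for n, p in gen.named_parameters()
                   if p.grad is None or not np.any(p.grad)]
        assert missing == []

    def test_block_order_changes_output(self, rng, tiny_gen_cfg):
        gen = Generator(rng, tiny_gen_cfg)
        lr = np.random.default_rng(0).uniform(0, 1, (3, 16, 16)).astype(np.float32)
        a = generator_forward(lr, gen)
        gen.cfg.block_order = "cam_then_rmb"
        b = generator_forward(lr, gen)
        assert not np.allclose(a, b)

    def test_post_upsampling_mode(self, rng):
        cfg = GeneratorConfig(base_channels=8, n_rmb=1, mpms_per_rmb=1, n_cam=1,
                              se_reduction=4, large_kernel=9, scale=4, upsampling="post")
        cfg.k1, cfg.k2 = 2, 4
        gen = Generator(rng, cfg)
        lr = rng.uniform(0, 1, (3, 16, 16)).astype(np.float32)
        assert generator_forward(lr, gen).shape == (3, 64, 64)

    def test_deterministic_given_state(self, rng, tiny_gen_cfg):
        gen = Generator(rng, tiny_gen_cfg)
        lr = np.random.default_rng(3).uniform(0, 1, (3, 16, 16)).astype(np.float32)
        assert np.array_equal(generator_forward(lr, gen), generator_forward(lr, gen))


class TestParameterCount:
    def test_single_conv_closed_form(self, rng):
        conv = Conv2d(rng, 3, 8, 3)
        assert conv.n_parameters() == 3 * 3 * 3 * 8 + 8

    def test_default_config_within_budget(self, rng):
        gen = Generator(rng, GeneratorConfig())
        assert count_parameters(gen) <= 500_000

    def test_count_independent_of_input(self, rng, tiny_gen_cfg):
        gen = Generator(rng, tiny_gen_cfg)
        n0 = count_parameters(gen)
        generator_forward(rng.uniform(0, 1, (3, 16, 16)).astype(np.float32), gen)
        assert count_parameters(gen) == n0
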