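"""Frequency-collaborative progressive generator.

The generator maps an LR image to an SR image ``scale`` times larger:

1. the input is split once into low/high-frequency components;
2. a trunk of residual multiscale blocks (RMBs, each a stack of
   mixed-pooling multiscale structures, MPMS) extracts multiscale features;
3. collaborative attention blocks (CAMs) exchange information between the
   high- and low-frequency feature streams;
4. progressive x2 sub-pixel stages (with a bilinear skip each) upsample,
   and a global bicubic skip carries the input to the output.

Where the architecture leaves width choices open, defaults are sized so the
whole generator stays within a few hundred thousand learned scalars; the
27x27 branch is depthwise for the same reason.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat
from .config import ConfigError, GeneratorConfig
from .frequency import decompose
from .resample import bicubic

__all__ = [
    "MPMS", "RMB", "CAM", "CBAMBlock", "UpsampleStage", "Generator",
    "k_sparse_channel_attention", "generator_forward", "count_parameters",
    "NumericalError",
]


class NumericalError(FloatingPointError):
    """Raised when an intermediate stage produces non-finite values."""

    def __init__(self, stage: str):
        super().__init__(f"non-finite values after stage {stage!r}")
        self.stage = stage


def _check(t: Tensor, stage: str) -> Tensor:
    if not np.isfinite(t.data).all():
        raise NumericalError(stage)
    return t


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class MPMS(nn.Module):
    """Mixed-pooling multiscale structure (three-branch block).

    Top: PReLU -> concat of dilated depthwise 3x3 convs (r in dilations) ->
    1x1 conv, plus a shared depthwise large-kernel branch, through an SE gate
    and PReLU -> multiscale features.  Bottom: 1x1 conv -> avg+max pooling
    plus the large-kernel branch -> 3x3 conv -> per-channel affine -> channel
    layer-norm -> hierarchical features.  Output: elementwise product.
    """

    def __init__(self, rng, c: int, cfg: GeneratorConfig):
        super().__init__()
        self.c = c
        self.act_in = nn.PReLU(c)
        self.dws = nn.ModuleList([nn.DWConv(rng, c, 3, dilation=r) for r in cfg.dilations])
        self.conv1_top = nn.Conv2d(rng, c * len(cfg.dilations), c, 1)
        self.dw_large = nn.DWConv(rng, c, cfg.large_kernel)
        self.se = nn.SEBlock(rng, c, cfg.se_reduction)
        self.act_out = nn.PReLU(c)
        self.conv1_bot = nn.Conv2d(rng, c, c, 1)
        self.conv3_tail = nn.Conv2d(rng, c, c, 3)
        self.affine = nn.ChannelAffine(c)
        # small initial norm gain keeps Fmix (and hence each RMB's residual
        # contribution) small at init, so deep stacks start near-identity
        self.norm = nn.LayerNormChannels(c, init_gain=0.1)

    def branches(self, fin: Tensor):
        if fin.shape[1] != self.c:
            raise ValueError(f"MPMS expects {self.c} channels, got {fin.shape[1]}")
        mid = self.dw_large(fin)  # shared large-receptive-field branch
        a = self.act_in(fin)
        f_in = concat([dw(a) for dw in self.dws], axis=1)
        f_mul = self.act_out(self.se(self.conv1_top(f_in) + mid))
        low = self.conv1_bot(fin)
        pre = F.avg_pool3(low) + F.max_pool3(low) + mid
        f_hie = self.norm(self.affine(self.conv3_tail(pre)))
        return f_mul, f_hie

    def forward(self, fin: Tensor) -> Tensor:
        f_mul, f_hie = self.branches(fin)
        return f_mul * f_hie


class RMB(nn.Module):
    """Residual multiscale block: stacked MPMS with a dual-residual path
    (long skip from the block input plus an inner skip from the first MPMS)."""

    def __init__(self, rng, c: int, cfg: GeneratorConfig):
        super().__init__()
        self.blocks = nn.ModuleList([MPMS(rng, c, cfg) for _ in range(cfg.mpms_per_rmb)])

    def forward(self, fin: Tensor) -> Tensor:
        y = fin
        first = None
        for i, blk in enumerate(self.blocks):
            y = blk(y)
            if i == 0:
                first = y
        if len(self.blocks) == 1:
            return fin + y
        return fin + first + y


def k_sparse_channel_attention(fl: Tensor, k1: int, k2: int, w1: float = 0.1,
                               w2: float = 0.3, masked_softmax: bool = False) -> Tensor:
    """K-sparse channel attention: keep the top-K1 channels of the mean-|x|
    score and the top-K2 channels of the spatial-variance score, combine as
    w1*s1 + w2*s2 on the kept channels, softmax over channels.

    Returns per-sample channel weights of shape (B, C, 1, 1) summing to 1.
    Ties in the top-K selection break toward the lower channel index; the
    selection itself is treated as a constant in the backward pass.
    """
    b, c = fl.shape[0], fl.shape[1]
    if k1 > c or k2 > c:
        raise ValueError(f"K1={k1}, K2={k2} must not exceed C={c}")
    s1 = fl.abs().mean(axis=(2, 3))  # (B, C)
    mu = fl.mean(axis=(2, 3))
    s2 = (fl * fl).mean(axis=(2, 3)) - mu * mu  # population variance
    mask1 = np.zeros((b, c), np.float32)
    mask2 = np.zeros((b, c), np.float32)
    for i in range(b):
        mask1[i, np.argsort(-s1.data[i], kind="stable")[:k1]] = 1.0
        mask2[i, np.argsort(-s2.data[i], kind="stable")[:k2]] = 1.0
    logits = s1 * Tensor(mask1 * np.float32(w1)) + s2 * Tensor(mask2 * np.float32(w2))
    if masked_softmax:
        union = (mask1 + mask2) > 0
        shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
        e = shifted.exp() * Tensor(union.astype(np.float32))
        weights = e / e.sum(axis=1, keepdims=True)
    else:
        weights = logits.softmax(axis=1)
    return weights.reshape(b, c, 1, 1)


def _dp_pool(x: Tensor, lam: float = 1.0) -> Tensor:
    """Detail-preserving pooling: 3x3 stride-1 average re-weighted toward
    locally high-contrast pixels, w = 1 + lam*|x - local mean|."""
    w = 1.0 + lam * (x - F.avg_pool3(x)).abs()
    num = F.avg_pool3(w * x)
    den = F.avg_pool3(w)
    return num / (den + 1e-8)


class _SpatialAttention(nn.Module):
    """CBAM-style spatial gate: 7x7 conv over [channel-mean; channel-max]."""

    def __init__(self, rng):
        super().__init__()
        self.conv = nn.Conv2d(rng, 2, 1, 7)

    def forward(self, x: Tensor) -> Tensor:
        desc = concat([x.mean(axis=1, keepdims=True), F.channel_max(x)], axis=1)
        return x * self.conv(desc).sigmoid()


class _ChannelAttention(nn.Module):
    """CBAM-style channel gate: shared MLP over avg- and max-pooled descriptors."""

    def __init__(self, rng, c: int, reduction: int = 8):
        super().__init__()
        mid = max(1, c // reduction)
        self.fc1 = nn.Conv2d(rng, c, mid, 1)
        self.fc2 = nn.Conv2d(rng, mid, c, 1)

    def forward(self, x: Tensor) -> Tensor:
        avg = F.global_avg_pool(x)
        mx = F.spatial_max(x)
        gate = (self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())).sigmoid()
        return x * gate


class _MLP1x1(nn.Module):
    """Channelwise MLP: two 1x1 convs with a PReLU between."""

    def __init__(self, rng, c: int):
        super().__init__()
        self.fc1 = nn.Conv2d(rng, c, c, 1)
        self.act = nn.PReLU(c)
        self.fc2 = nn.Conv2d(rng, c, c, 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.act(self.fc1(x)))


class CAM(nn.Module):
    """Collaborative attention: a high-frequency branch (detail-preserving
    pooling, parallel spatial/channel attention) and a low-frequency branch
    (SE features, K-sparse channel attention) that exchange channel weights
    and an MLP-transformed detail tensor."""

    def __init__(self, rng, c: int, cfg: GeneratorConfig):
        super().__init__()
        self.c = c
        self.cfg = cfg
        # high branch
        self.conv1_h = nn.Conv2d(rng, c, c, 1)
        self.sa = _SpatialAttention(rng)
        self.ca = _ChannelAttention(rng, c, cfg.se_reduction)
        self.norm_h = nn.LayerNormChannels(2 * c)
        self.conv3_h = nn.Conv2d(rng, 2 * c, c, 3)
        self.mlp_h = _MLP1x1(rng, c)   # FMLPh fed to the low branch
        self.mlp_out = _MLP1x1(rng, c)
        self.conv3_out = nn.Conv2d(rng, c, c, 3)
        self.conv1_fh = nn.Conv2d(rng, c, c, 1)
        # gain < 1 on the output projections: the two summed branches would
        # otherwise grow the (non-residual) stream by ~sqrt(2) per block
        self.lin_h = nn.Conv2d(rng, c, c, 1, gain=0.5)
        # low branch
        self.conv1_l = nn.Conv2d(rng, c, c, 1)
        self.conv3_l = nn.Conv2d(rng, c, c, 3)
        self.se_l = nn.SEBlock(rng, c, cfg.se_reduction)
        self.conv1_fl = nn.Conv2d(rng, c, c, 1)
        self.conv1_fl_skip = nn.Conv2d(rng, c, c, 1)
        self.lin_l = nn.Conv2d(rng, c, c, 1, gain=0.5)

    def forward(self, fh: Tensor, fl: Tensor):
        if fh.shape != fl.shape:
            raise ValueError(f"CAM stream shape mismatch: {fh.shape} vs {fl.shape}")
        # high branch
        t = self.conv1_h(_dp_pool(fh))
        fh_hat = concat([self.sa(t), self.ca(t)], axis=1)
        fh_prime = self.conv3_h(self.norm_h(fh_hat))  # back to C channels
        # low branch
        fl_hat = self.se_l(self.conv3_l(self.conv1_l(fl)))
        w = k_sparse_channel_attention(
            fl_hat, self.cfg.K1, self.cfg.K2, self.cfg.kspa_w1, self.cfg.kspa_w2,
            self.cfg.kspa_masked_softmax,
        )
        f_mix = w * self.conv1_fl(fl) * self.mlp_h(fh_prime)
        out_h = self.lin_h(self.conv3_out(self.mlp_out(fh_prime * w)) + self.conv1_fh(fh))
        out_l = self.lin_l(self.conv1_fl_skip(f_mix) + self.conv1_fl(fl))
        return out_h, out_l


class CBAMBlock(nn.Module):
    """Plain CBAM block (channel gate then spatial gate around a conv),
    applied to each frequency stream independently — the ablation baseline
    the collaborative block is compared against."""

    def __init__(self, rng, c: int, cfg: GeneratorConfig):
        super().__init__()
        self.conv_h = nn.Conv2d(rng, c, c, 3)
        self.conv_l = nn.Conv2d(rng, c, c, 3)
        self.ca_h = _ChannelAttention(rng, c, cfg.se_reduction)
        self.sa_h = _SpatialAttention(rng)
        self.ca_l = _ChannelAttention(rng, c, cfg.se_reduction)
        self.sa_l = _SpatialAttention(rng)

    def forward(self, fh: Tensor, fl: Tensor):
        return (
            fh + self.sa_h(self.ca_h(self.conv_h(fh))),
            fl + self.sa_l(self.ca_l(self.conv_l(fl))),
        )


class UpsampleStage(nn.Module):
    """x2 sub-pixel stage: Conv3 to 4C -> pixel shuffle -> PReLU, plus a
    bilinear x2 skip of the input (the 'partial skip' of progressive mode)."""

    def __init__(self, rng, c: int):
        super().__init__()
        self.conv = nn.Conv2d(rng, c, 4 * c, 3)
        self.act = nn.PReLU(c)

    def forward(self, x: Tensor) -> Tensor:
        y = self.act(F.pixel_shuffle2(self.conv(x)))
        return y + F.bilinear_up2(x)


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

class Generator(nn.Module):
    def __init__(self, rng: np.random.Generator, cfg: GeneratorConfig):
        super().__init__()
        errs: list[str] = []
        cfg.validate(errs)
        if errs:
            raise ConfigError(errs)
        self.cfg = cfg
        c = cfg.base_channels
        self.shallow_lr = nn.Conv2d(rng, 3, c, 3)
        self.shallow_h = nn.Conv2d(rng, 3, c, 3)
        self.shallow_l = nn.Conv2d(rng, 3, c, 3)
        self.rmbs = nn.ModuleList([RMB(rng, c, cfg) for _ in range(cfg.n_rmb)])
        block = CAM if cfg.attention == "cam" else CBAMBlock
        self.cams = nn.ModuleList([block(rng, c, cfg) for _ in range(cfg.n_cam)])
        self.merge = nn.Conv2d(rng, c, c, 1)
        n_stages = int(np.log2(cfg.scale))
        if cfg.upsampling == "progressive":
            self.up = nn.ModuleList([UpsampleStage(rng, c) for _ in range(n_stages)])
        else:  # post: a single (scale^2 * C)-channel shuffle
            self.up_conv = nn.Conv2d(rng, c, (cfg.scale ** 2) * c, 3)
        # small output gain keeps the initial model close to its bicubic skip
        self.out_conv = nn.Conv2d(rng, c, 3, 3, gain=0.01)

    # frequency decomposition applied once, to the LR input
    def _split(self, lr_np: np.ndarray):
        if self.cfg.fd_method == "none":
            return lr_np, lr_np
        pairs = [decompose(im, self.cfg.fd_sigma, self.cfg.fd_ksize, self.cfg.fd_method)
                 for im in lr_np]
        low = np.stack([p.low for p in pairs])
        high = np.stack([p.high for p in pairs])
        return high, low

    def forward(self, lr: Tensor, clip: bool = True) -> Tensor:
        """SR forward pass.  ``clip=False`` returns the unclipped output: the
        training loop uses it so saturated pixels keep their gradients (a
        clipped pixel would be stuck at 0/1 for the rest of the run)."""
        if lr.ndim != 4 or lr.shape[1] != 3:
            raise ValueError(f"expected (B,3,H,W) LR batch, got {lr.shape}")
        cfg = self.cfg
        xh_np, xl_np = self._split(lr.data)
        xh, xl = Tensor(xh_np), Tensor(xl_np)
        skip = Tensor(np.stack([bicubic(im, cfg.scale) for im in lr.data]))

        if cfg.block_order == "rmb_then_cam":
            trunk = self.shallow_lr(lr)
            for rmb in self.rmbs:
                trunk = rmb(trunk)
            _check(trunk, "rmb_trunk")
            fh = trunk + self.shallow_h(xh)
            fl = trunk + self.shallow_l(xl)
            for cam in self.cams:
                fh, fl = cam(fh, fl)
            _check(fh, "cam_high")
            merged = self.merge(fh + fl)
        else:  # cam_then_rmb ablation: attention first, trunk after
            fh = self.shallow_h(xh)
            fl = self.shallow_l(xl)
            for cam in self.cams:
                fh, fl = cam(fh, fl)
            merged = self.merge(fh + fl) + self.shallow_lr(lr)
            for rmb in self.rmbs:
                merged = rmb(merged)
            _check(merged, "rmb_trunk")

        if cfg.upsampling == "progressive":
            up = merged
            for stage in self.up:
                up = stage(up)
        else:
            up = self.up_conv(merged)
            for _ in range(int(np.log2(cfg.scale))):
                up = F.pixel_shuffle2(up)
        _check(up, "upsample")
        out = self.out_conv(up) + skip
        _check(out, "output")
        return out.clip01() if clip else out


def generator_forward(lr: np.ndarray, model: Generator) -> np.ndarray:
    """Run one (3, H, W) LR image through the generator, returning the
    (3, scale*H, scale*W) SR image as numpy."""
    if lr.min() < 0 or lr.max() > 1:
        raise ValueError("LR input must lie in [0, 1]")
    out = model(Tensor(lr[None]))
    return out.data[0]


def count_parameters(model: nn.Module) -> int:
    """Exact count of learned scalars."""
    return model.n_parameters()
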