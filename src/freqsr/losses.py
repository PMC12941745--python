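"""Training losses for the adversarial super-resolution model.

Four terms drive the generator:

* adversarial:  L_adv = sum_n -log D(G(lr_n))   (non-saturating form);
* spatial consistency: neighbour-difference distance between deep-feature
  cell means of the SR output and of the bicubically upsampled LR input;
* color constancy: gray-world penalty on the channel means of the output;
* the combined perceptual loss  L_per = L_spa + lambda1*L_col + lambda2*L_adv
  with defaults lambda1 = 0.1, lambda2 = 1e-3.

The deep-feature extractor is pluggable.  The always-available backend is a
fixed (never trained) randomly initialized conv stack, seeded and
deterministic, so the package needs no pretrained-weight download; a
pretrained VGG19 backend can be requested but raises a clear error when no
deep-learning runtime provides it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor
from .config import LossWeights

__all__ = [
    "FeatureExtractor", "RandomFeatureExtractor", "make_feature_extractor",
    "LossBundle", "adversarial_loss", "discriminator_loss",
    "spatial_consistency_loss", "color_constancy_loss", "perceptual_loss",
    "BackendUnavailableError",
]

_EPS = 1e-7  # probability clamp


class BackendUnavailableError(RuntimeError):
    pass


class FeatureExtractor:
    """Interface: a fixed, deterministic map from an image batch tensor
    (B, 3, H, W) to a feature tensor (B, C', H', W')."""

    def __call__(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError


class IdentityFeatures(FeatureExtractor):
    """Pass-through features; handy for closed-form tests of the cell sums."""

    def __call__(self, x: Tensor) -> Tensor:
        return x


class RandomFeatureExtractor(FeatureExtractor):
    """Fixed-random conv stack: three 3x3 convs with LeakyReLU between,
    weights drawn once from ``seed`` and never trained.  Synthetic stand-in
    feature space (not a pretrained perceptual network): it provides a
    deterministic, spatially local, nonlinear embedding.

    Convolutions are *valid* (no padding): a spatially constant image then
    keeps spatially constant features, so border padding can never leak
    artificial structure into the consistency cells.
    """

    def __init__(self, seed: int = 0, channels: int = 16, n_layers: int = 3):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFEA7]))
        self.layers = []
        cin = 3
        for _ in range(n_layers):
            conv = nn.Conv2d(rng, cin, channels, 3)
            conv.weight.requires_grad = False
            conv.bias.requires_grad = False
            self.layers.append(conv)
            cin = channels

    def __call__(self, x: Tensor) -> Tensor:
        from .nn import functional as F

        for i, conv in enumerate(self.layers):
            x = F.conv2d(x, conv.weight, conv.bias, padding=0)
            if i < len(self.layers) - 1:
                x = x.leaky_relu(0.2)
        return x


def make_feature_extractor(w: LossWeights, seed: int = 0) -> FeatureExtractor:
    if w.features == "random":
        return RandomFeatureExtractor(seed)
    raise BackendUnavailableError(
        "pretrained VGG19 features require a deep-learning runtime that is "
        "not installed; use loss.features='random'"
    )


@dataclass
class LossBundle:
    adv: float
    spa: float
    col: float
    per: float


def _clamp_probs(p: Tensor) -> Tensor:
    return Tensor(np.clip(p.data, _EPS, 1.0 - _EPS)) if not p.requires_grad else _clamp_grad(p)


def _clamp_grad(p: Tensor) -> Tensor:
    lo, hi = _EPS, 1.0 - _EPS
    mask = (p.data > lo) & (p.data < hi)

    def bwd(g):
        p._accum(g * mask)

    return Tensor._make(np.clip(p.data, lo, hi), (p,), bwd)


def adversarial_loss(d_probs: Tensor) -> Tensor:
    """Non-saturating generator loss: sum_n -log p_n over the batch."""
    if d_probs.data.size == 0:
        raise ValueError("empty batch of probabilities")
    return -(_clamp_probs(d_probs).log().sum())


def discriminator_loss(p_real: Tensor, p_fake: Tensor) -> Tensor:
    """-sum log p_real - sum log(1 - p_fake)."""
    if p_real.data.size == 0 or p_fake.data.size == 0:
        raise ValueError("empty probability vectors")
    pr = _clamp_probs(p_real)
    pf = _clamp_probs(p_fake)
    return -(pr.log().sum()) - ((1.0 - pf).log().sum())


def _cell_means(feat: Tensor, region: int) -> Tensor:
    """Non-overlapping region x region cell means of (B, C, H, W) features;
    trailing rows/cols that do not fill a cell are dropped."""
    b, c, h, w = feat.shape
    gh, gw = h // region, w // region
    if gh < 1 or gw < 1:
        raise ValueError(f"feature map {h}x{w} smaller than one {region}x{region} cell")
    cropped = feat[:, :, : gh * region, : gw * region]
    return cropped.reshape(b, c, gh, region, gw, region).mean(axis=(3, 5))


def spatial_consistency_loss(y: Tensor, ref: Tensor, fx: FeatureExtractor,
                             region: int = 4) -> Tensor:
    """Neighbour-difference consistency between SR output and reference.

    The caller upsamples the LR reference to y's size beforehand (bicubic).
    Features of both are partitioned into region x region cells; for every
    cell and each of its 4-connected neighbours the squared difference of
    |cell-mean gaps| is accumulated over channels and divided by the number
    of cells K.
    """
    if y.shape != ref.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {ref.shape} (upsample ref first)")
    my = _cell_means(fx(y), region)
    mr = _cell_means(fx(ref), region)
    k = my.shape[2] * my.shape[3]
    total = None
    # ordered 4-neighbour pairs via axis shifts (down/up/right/left)
    for axis, shift in ((2, 1), (2, -1), (3, 1), (3, -1)):
        sl_a = [slice(None)] * 4
        sl_b = [slice(None)] * 4
        sl_a[axis] = slice(1, None) if shift == 1 else slice(None, -1)
        sl_b[axis] = slice(None, -1) if shift == 1 else slice(1, None)
        dy = (my[tuple(sl_a)] - my[tuple(sl_b)]).abs()
        dr = (mr[tuple(sl_a)] - mr[tuple(sl_b)]).abs()
        term = ((dy - dr) ** 2.0).sum()
        total = term if total is None else total + term
    return total * (1.0 / k)


def color_constancy_loss(y: Tensor) -> Tensor:
    """Gray-world penalty: sum over channel pairs of squared mean gaps."""
    ch_axis = 1 if y.ndim == 4 else 0
    if y.shape[ch_axis] != 3:
        raise ValueError(f"color constancy needs 3 channels, got {y.shape[ch_axis]}")
    j = y.mean(axis=(0, 2, 3)) if y.ndim == 4 else y.mean(axis=(1, 2))
    jr, jg, jb = j[0], j[1], j[2]
    return (jr - jg) ** 2.0 + (jr - jb) ** 2.0 + (jg - jb) ** 2.0


def perceptual_loss(spa, col, adv, w: LossWeights):
    """L_per = L_spa + lambda1 * L_col + lambda2 * L_adv.

    Accepts autodiff scalars (training path) or plain floats (reporting path,
    evaluated in double precision)."""
    if w.lambda1 < 0 or w.lambda2 < 0:
        raise ValueError("loss weights must be non-negative")
    if not isinstance(spa, Tensor) and not isinstance(col, Tensor) and not isinstance(adv, Tensor):
        return float(spa) + w.lambda1 * float(col) + w.lambda2 * float(adv)
    return spa + w.lambda1 * col + w.lambda2 * adv
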