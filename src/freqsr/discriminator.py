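"""VGG-style image-perceptual discriminator.

Maps an RGB image to the probability that it is a real (rather than
super-resolved) HR image: a shallow conv, a cascade of stride-2 conv /
batch-norm / LeakyReLU stages with doubling channel counts, then a final
conv, global average pooling and a sigmoid head.  Global pooling makes the
head independent of the crop size, so the same discriminator evaluates
64x64 training crops and 128/256 SR outputs.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor
from .config import ConfigError, DiscriminatorConfig

__all__ = ["Discriminator", "discriminator_forward"]

_SLOPE = 0.2  # LeakyReLU slope, standard for SR discriminators


class Discriminator(nn.Module):
    def __init__(self, rng: np.random.Generator, cfg: DiscriminatorConfig):
        super().__init__()
        errs: list[str] = []
        cfg.validate(errs)
        if errs:
            raise ConfigError(errs)
        self.cfg = cfg
        c = cfg.base_channels
        self.shallow = nn.Conv2d(rng, 3, c, 3)
        convs, norms = [], []
        cin = c
        for k in range(cfg.n_stages):
            cout = min(c * (2 ** (k + 1)), c * 8)  # doubling, capped at 8x base
            convs.append(nn.Conv2d(rng, cin, cout, 3, stride=2))
            norms.append(nn.BatchNorm2d(cout))
            cin = cout
        self.convs = nn.ModuleList(convs)
        self.norms = nn.ModuleList(norms)
        self.final_conv = nn.Conv2d(rng, cin, cin, 3)
        self.final_norm = nn.BatchNorm2d(cin)
        self.head = nn.Conv2d(rng, cin, 1, 1)

    def forward(self, img: Tensor) -> Tensor:
        """(B, 3, H, W) -> (B,) probabilities strictly in (0, 1)."""
        if img.ndim != 4 or img.shape[1] != 3:
            raise ValueError(f"expected (B,3,H,W), got {img.shape}")
        if min(img.shape[2], img.shape[3]) < 2 ** self.cfg.n_stages:
            raise ValueError(
                f"input side {img.shape[2:]} smaller than total stride "
                f"{2 ** self.cfg.n_stages}"
            )
        x = self.shallow(img).leaky_relu(_SLOPE)
        for conv, norm in zip(self.convs, self.norms):
            x = norm(conv(x)).leaky_relu(_SLOPE)
        x = self.final_norm(self.final_conv(x)).leaky_relu(_SLOPE)
        p = self.head(F.global_avg_pool(x)).sigmoid()
        return p.reshape(p.shape[0])


def discriminator_forward(img: np.ndarray, model: Discriminator) -> float:
    """Probability that a single (3, H, W) image is a real HR image
    (inference mode: batch-norm uses running statistics)."""
    was_training = model.training
    model.eval()
    try:
        p = model(Tensor(img[None]))
    finally:
        model.train(was_training)
    return float(p.data[0])
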