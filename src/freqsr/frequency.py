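"""Additive frequency decomposition of images / feature maps.

The low-frequency component is a smoothing-filter response (Gaussian by
default; guided- and bilateral-filter variants share the interface for
ablations) and the high-frequency component is defined by subtraction,
so ``low + high`` reconstructs the input at machine precision by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate, uniform_filter
from skimage.restoration import denoise_bilateral

from .config import BlurKernel
from .degradation import anisotropic_gaussian_kernel

__all__ = ["FrequencyPair", "decompose", "gaussian_kernel2d"]


@dataclass(frozen=True)
class FrequencyPair:
    low: np.ndarray
    high: np.ndarray

    @property
    def reconstruction(self) -> np.ndarray:
        return self.low + self.high


def gaussian_kernel2d(sigma: float, ksize: int) -> np.ndarray:
    """Normalized isotropic 2-D Gaussian sampled on a ksize x ksize grid."""
    if ksize % 2 == 0 or ksize < 3:
        raise ValueError(f"ksize must be odd and >= 3, got {ksize}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return anisotropic_gaussian_kernel(
        BlurKernel(size=ksize, sigma_major=sigma, sigma_minor=sigma, theta=0.0)
    )


def _guided_filter(x: np.ndarray, radius: int = 4, eps: float = 1e-3) -> np.ndarray:
    """Self-guided edge-preserving filter (box-window linear model) per channel."""
    size = 2 * radius + 1

    def box(a):
        return uniform_filter(a, size=size, mode="reflect")

    out = np.empty_like(x, dtype=np.float64)
    for i, ch in enumerate(x.astype(np.float64)):
        mu = box(ch)
        var = box(ch * ch) - mu * mu
        a = var / (var + eps)
        b = mu - a * mu
        out[i] = box(a) * ch + box(b)
    return out


def decompose(x: np.ndarray, sigma: float = 2.0, ksize: int = 13,
              method: str = "gaussian") -> FrequencyPair:
    """Split (C, H, W) into low = smooth(x), high = x - low (shape preserved).

    ``method`` selects the smoother: 'gaussian' (convolutional Gaussian with
    reflective padding; the default), 'guided', or 'bilateral'.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError(f"expected (C,H,W), got shape {x.shape}")
    if method == "gaussian":
        kern = gaussian_kernel2d(sigma, ksize)
        low = np.stack([correlate(ch.astype(np.float64), kern, mode="reflect") for ch in x])
    elif method == "guided":
        low = _guided_filter(x)
    elif method == "bilateral":
        hwc = np.ascontiguousarray(np.clip(x, 0.0, 1.0).transpose(1, 2, 0).astype(np.float64))
        low = denoise_bilateral(hwc, sigma_color=0.1, sigma_spatial=sigma, channel_axis=-1)
        low = low.transpose(2, 0, 1)
    else:
        raise ValueError(f"unknown decomposition method {method!r}")
    low = low.astype(np.float32)
    return FrequencyPair(low=low, high=x - low)
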