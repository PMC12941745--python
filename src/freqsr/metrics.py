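"""Image quality metrics: PSNR, SSIM, and an optional perceptual (LPIPS-style)
backend.

PSNR and SSIM operate on [0,1] channel-first images (``peak`` rescales the
formulas for other conventions, e.g. ``peak=255``).  Both are computed on RGB
directly — no luma conversion — and that choice is recorded in report headers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

from .frequency import gaussian_kernel2d
from .losses import BackendUnavailableError, RandomFeatureExtractor
from .nn.tensor import Tensor

__all__ = [
    "MetricReport", "psnr", "ssim", "lpips", "SyntheticPerceptualBackend",
    "evaluate_pairs",
]

_SSIM_WIN = 11
_SSIM_SIGMA = 1.5


@dataclass
class MetricReport:
    psnr: float
    ssim: float
    lpips: float | None = None

    def to_json(self) -> dict:
        out = {"psnr": "inf" if math.isinf(self.psnr) else self.psnr, "ssim": self.ssim}
        if self.lpips is not None:
            out["lpips"] = self.lpips
        return out


def _check_pair(ref, test):
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return ref, test


def psnr(ref: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """10*log10(peak^2 / MSE) over all pixels and channels; identical images
    give +inf."""
    ref, test = _check_pair(ref, test)
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak * peak / mse)


def ssim(ref: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Mean structural similarity over sliding 11x11 Gaussian windows
    (sigma 1.5), C1=(0.01*peak)^2, C2=(0.03*peak)^2, averaged over channels.

    Windowed means/variances use the Gaussian weights (population form); the
    half-window border is cropped before averaging so padding never enters.
    """
    ref, test = _check_pair(ref, test)
    if min(ref.shape[-2], ref.shape[-1]) < _SSIM_WIN:
        raise ValueError(f"image smaller than the {_SSIM_WIN}x{_SSIM_WIN} window")
    kern = gaussian_kernel2d(_SSIM_SIGMA, _SSIM_WIN)
    c1 = (0.01 * peak) ** 2
    c2 = (0.03 * peak) ** 2
    pad = (_SSIM_WIN - 1) // 2

    def smooth(a):
        return correlate(a, kern, mode="reflect")

    vals = []
    for x, y in zip(ref, test):
        ux, uy = smooth(x), smooth(y)
        vx = smooth(x * x) - ux * ux
        vy = smooth(y * y) - uy * uy
        cxy = smooth(x * y) - ux * uy
        s = ((2 * ux * uy + c1) * (2 * cxy + c2)) / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
        vals.append(s[pad:-pad, pad:-pad].mean())
    return float(np.mean(vals))


class SyntheticPerceptualBackend:
    """LPIPS-style distance over a fixed random conv stack (synthetic stand-in
    feature space, not a pretrained perceptual network).

    For each layer l: unit-normalize the channel vector at every position,
    then accumulate (1/(H_l W_l)) * sum_{h,w} ||w_l (y - y_hat)||^2 with fixed
    positive channel weights w_l.
    """

    def __init__(self, seed: int = 0, channels: int = 8):
        self._fx = RandomFeatureExtractor(seed, channels=channels)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11F5]))
        self._weights = [
            rng.uniform(0.2, 1.0, size=channels).astype(np.float32)
            for _ in self._fx.layers
        ]

    def _features(self, img: np.ndarray):
        x = Tensor(img[None].astype(np.float32))
        feats = []
        for i, conv in enumerate(self._fx.layers):
            x = conv(x)
            if i < len(self._fx.layers) - 1:
                x = x.leaky_relu(0.2)
            feats.append(x.data[0])
        return feats

    @staticmethod
    def _unit(f: np.ndarray) -> np.ndarray:
        norm = np.sqrt((f * f).sum(axis=0, keepdims=True)) + 1e-10
        return f / norm

    def distance(self, ref: np.ndarray, test: np.ndarray) -> float:
        total = 0.0
        for f1, f2, w in zip(self._features(ref), self._features(test), self._weights):
            d = w[:, None, None] * (self._unit(f1) - self._unit(f2))
            total += float((d * d).sum() / (d.shape[1] * d.shape[2]))
        return total


def lpips(ref: np.ndarray, test: np.ndarray, backend=None) -> float:
    """Perceptual distance delegated to ``backend`` (an object with a
    ``distance(ref, test)`` method, e.g. a pretrained LPIPS wrapper or the
    synthetic backend above).  Without a backend this metric is unavailable
    and raises — it never silently returns 0."""
    ref, test = _check_pair(ref, test)
    if backend is None:
        raise BackendUnavailableError(
            "optional metric unavailable: LPIPS needs a perceptual backend "
            "(no pretrained network is installed); pass one explicitly"
        )
    return float(backend.distance(ref, test))


def evaluate_pairs(pairs, metrics=("psnr", "ssim"), backend=None, peak: float = 1.0) -> dict:
    """Score (reconstruction, reference) pairs; returns per-image reports plus
    mean and standard deviation per metric."""
    reports = []
    for test, ref in pairs:
        rep = MetricReport(
            psnr=psnr(ref, test, peak) if "psnr" in metrics else math.nan,
            ssim=ssim(ref, test, peak) if "ssim" in metrics else math.nan,
            lpips=lpips(ref, test, backend) if "lpips" in metrics else None,
        )
        reports.append(rep)

    def stats(vals):
        finite = [v for v in vals if v is not None and not math.isinf(v)]
        if not finite:
            return {"mean": "inf", "sd": 0.0}
        return {"mean": float(np.mean(finite)), "sd": float(np.std(finite))}

    summary = {"colorspace": "RGB"}
    if "psnr" in metrics:
        summary["psnr"] = stats([r.psnr for r in reports])
    if "ssim" in metrics:
        summary["ssim"] = stats([r.ssim for r in reports])
    if "lpips" in metrics:
        summary["lpips"] = stats([r.lpips for r in reports])
    return {"per_image": [r.to_json() for r in reports], "summary": summary}
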