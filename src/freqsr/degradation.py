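"""Real-noise degradation pipeline.

Synthetic LR training inputs are produced from HR images by anisotropic
Gaussian blur, decimation, and injection of *real* noise: zero-mean residual
patches harvested from smooth regions of (real or emulated) low-resolution
images.  A global patch P (side ``d``) is *smooth* when every local
sub-patch Q inside it matches P's mean and population variance within
relative tolerances alpha and beta:

    |Mean(Q) - Mean(P)| <= alpha * Mean(P)   and
    |Var(Q)  - Var(P) | <= beta  * Var(P)    for every Q.

Smooth patches, mean-subtracted per channel, form the noise pool; sampling
tiles a target shape with randomly drawn, randomly flipped pool members.

Patches follow the package-wide channel-first (C, d, d) layout.  Windows are
0-based, row-major, half-open [r, r+d).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import correlate

from .config import BlurKernel, DegradationConfig, PatchWindow
from .resample import bicubic

__all__ = [
    "NoisePool", "is_smooth_patch", "collect_noise_pool", "sample_noise",
    "anisotropic_gaussian_kernel", "degrade", "EmptyPoolError",
]

# Eq. 2 is ill-posed when Mean(P) (or Var(P)) is 0: the right-hand side
# collapses to 0, so the test degenerates to exact equality at this tolerance.
_DEGENERATE_TOL = 1e-12


class EmptyPoolError(RuntimeError):
    pass


@dataclass
class NoisePool:
    """Zero-mean residual patches plus per-patch source metadata."""

    patches: list = field(default_factory=list)  # (C, d, d) float32 arrays
    sources: list = field(default_factory=list)  # (image_index, row, col)

    def __len__(self):
        return len(self.patches)

    @property
    def d(self) -> int:
        if not self.patches:
            raise EmptyPoolError("noise pool is empty")
        return self.patches[0].shape[-1]

    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(path, *[p.astype(np.float32) for p in self.patches])
        meta = {"n": len(self.patches), "sources": [list(map(int, s)) for s in self.sources]}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "NoisePool":
        path = Path(path)
        with np.load(path) as z:
            patches = [z[k] for k in sorted(z.files, key=lambda s: int(s.split("_")[1]))]
        sidecar = path.with_suffix(".json")
        sources = []
        if sidecar.exists():
            sources = [tuple(s) for s in json.loads(sidecar.read_text())["sources"]]
        return cls(patches=patches, sources=sources)


def _mean_var(patch: np.ndarray):
    """Pooled mean and population variance over all pixels and channels."""
    flat = patch.reshape(-1).astype(np.float64)
    return flat.mean(), flat.var()


def is_smooth_patch(patch: np.ndarray, window: PatchWindow) -> bool:
    """True iff every local sub-patch matches the global mean/variance bounds."""
    d, dl, sl = window.d, window.dl, window.sl
    if patch.shape[-1] != d or patch.shape[-2] != d:
        raise ValueError(f"patch side must be d={d}, got {patch.shape}")
    if d <= dl:
        raise ValueError("local side dl must be smaller than d")
    mp, vp = _mean_var(patch)
    for r in range(0, d - dl + 1, sl):
        for c in range(0, d - dl + 1, sl):
            mq, vq = _mean_var(patch[..., r : r + dl, c : c + dl])
            lhs_m = abs(mq - mp)
            rhs_m = window.alpha * mp
            if (lhs_m > rhs_m) if mp > 0 else (lhs_m > _DEGENERATE_TOL):
                return False
            lhs_v = abs(vq - vp)
            rhs_v = window.beta * vp
            if (lhs_v > rhs_v) if vp > 0 else (lhs_v > _DEGENERATE_TOL):
                return False
    return True


def collect_noise_pool(images, window: PatchWindow, logger=None) -> NoisePool:
    """Scan images (stride ``sg``, row-major) and pool mean-subtracted smooth
    patches.  An empty result is valid (and logged when a logger is given)."""
    pool = NoisePool()
    d, sg = window.d, window.sg
    for idx, img in enumerate(images):
        c, h, w = img.shape
        if h < d or w < d:
            raise ValueError(f"image {idx} smaller than patch side d={d}")
        for r in range(0, h - d + 1, sg):
            for cc in range(0, w - d + 1, sg):
                patch = img[:, r : r + d, cc : cc + d]
                if is_smooth_patch(patch, window):
                    resid = patch - patch.mean(axis=(1, 2), keepdims=True)
                    pool.patches.append(resid.astype(np.float32))
                    pool.sources.append((idx, r, cc))
    if logger is not None and len(pool) == 0:
        logger.info("noise pool is empty: no smooth patches found")
    return pool


def sample_noise(pool: NoisePool, rng: np.random.Generator, shape) -> np.ndarray:
    """Tile ``shape`` (H, W) with independently drawn pool patches (random
    index, random horizontal/vertical flips) and crop."""
    if len(pool) == 0:
        raise EmptyPoolError(
            "noise pool is empty; use noise_mode='gaussian' as a fallback"
        )
    h, w = shape
    d = pool.d
    if h < d or w < d:
        raise ValueError(f"target {shape} smaller than patch side d={d}")
    c = pool.patches[0].shape[0]
    ny, nx = -(-h // d), -(-w // d)
    out = np.empty((c, ny * d, nx * d), np.float32)
    for i in range(ny):
        for j in range(nx):
            p = pool.patches[int(rng.integers(len(pool)))]
            if rng.integers(2):
                p = p[:, :, ::-1]
            if rng.integers(2):
                p = p[:, ::-1, :]
            out[:, i * d : (i + 1) * d, j * d : (j + 1) * d] = p
    return out[:, :h, :w]


def anisotropic_gaussian_kernel(k: BlurKernel) -> np.ndarray:
    """Sample K(x) ~ exp(-x' Sigma^-1 x / 2) on the centred integer grid and
    normalize to sum 1; Sigma = R(theta) diag(sM^2, sm^2) R(theta)'."""
    if k.sigma_major <= 0 or k.sigma_minor <= 0:
        raise ValueError("kernel sigmas must be positive")
    half = (k.size - 1) // 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    ct, st = np.cos(k.theta), np.sin(k.theta)
    # rotate coordinates into the kernel's principal frame
    u = ct * xx + st * yy
    v = -st * xx + ct * yy
    q = (u / k.sigma_major) ** 2 + (v / k.sigma_minor) ** 2
    kern = np.exp(-0.5 * q)
    return (kern / kern.sum()).astype(np.float64)


def blur(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Per-channel 2-D correlation with reflective (symmetric) padding."""
    return np.stack([correlate(ch.astype(np.float64), kernel, mode="reflect") for ch in img])


def degrade(hr: np.ndarray, cfg: DegradationConfig, pool: NoisePool | None = None,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """HR -> LR: blur with the anisotropic kernel, decimate by ``scale``
    (or bicubic-downsample in the ablation mode), add noise, clip to [0, 1]."""
    s = cfg.scale
    if hr.shape[1] % s or hr.shape[2] % s:
        raise ValueError(f"hr dims {hr.shape[1:]} not divisible by scale {s}")
    if cfg.downsample == "bicubic":
        lr = bicubic(hr, 1.0 / s) if s > 1 else hr.astype(np.float64)
    else:
        kern = anisotropic_gaussian_kernel(cfg.kernel)
        blurred = blur(hr, kern)
        lr = blurred[:, ::s, ::s]
    if cfg.noise_mode == "pool":
        if pool is None or len(pool) == 0:
            raise EmptyPoolError("noise_mode='pool' requires a non-empty noise pool")
        if rng is None:
            raise ValueError("pool noise requires an rng")
        lr = lr + sample_noise(pool, rng, lr.shape[1:])
    elif cfg.noise_mode == "gaussian":
        if rng is None:
            raise ValueError("gaussian noise requires an rng")
        lr = lr + rng.normal(0.0, cfg.noise_sigma, size=lr.shape)
    return np.clip(lr, 0.0, 1.0).astype(np.float32)
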