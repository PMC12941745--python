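"""Deterministic synthetic high-resolution image generator.

Every stage of the pipeline is testable without downloading a dataset: this
module fabricates HR images covering the feature classes the method cares
about — flat regions (smooth-patch detection), strong edges (detail
enhancement), periodic texture (aliasing stress) and nucleus-like blob fields
on a pink-ish background that emulate H&E histology patches.

All generation is a pure function of the spec (kind, size, seed, noise);
the same spec always yields the bit-identical array.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .degradation import degrade

__all__ = ["FixtureSpec", "make_hr_image", "make_dataset", "default_specs", "split_dataset"]

KINDS = ("gradient", "checkerboard", "texture", "blobs")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str = "blobs"
    size: tuple = (64, 64)
    seed: int = 0
    noise_sigma: float = 0.0  # additive Gaussian sensor-noise emulation
    block: int = 2  # checkerboard block side

    def validate(self):
        h, w = self.size
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if h % 4 or w % 4:
            raise ValueError(f"fixture size must be divisible by 4, got {self.size}")
        if not (0 <= self.noise_sigma < 0.5):
            raise ValueError(f"noise_sigma must lie in [0, 0.5), got {self.noise_sigma}")
        return self


def _gradient(h, w, rng):
    col = np.linspace(0.0, 1.0, h, dtype=np.float32) if h > 1 else np.zeros(1, np.float32)
    img = np.broadcast_to(col[:, None], (h, w))
    return np.repeat(img[None], 3, axis=0).copy()


def _checkerboard(h, w, rng, block):
    r = np.arange(h)[:, None] // block
    c = np.arange(w)[None, :] // block
    img = ((r + c) % 2).astype(np.float32)
    return np.repeat(img[None], 3, axis=0)


def _texture(h, w, rng):
    # band-limited random field with a few hard edges; near-gray with a mild tint
    field = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0, mode="reflect")
    lo, hi = field.min(), field.max()
    field = (field - lo) / max(hi - lo, 1e-9)
    edges = gaussian_filter(rng.standard_normal((h, w)), sigma=6.0, mode="reflect")
    mask = edges > np.median(edges)
    field = np.where(mask, 0.25 + 0.5 * field, 0.05 + 0.5 * field)
    tints = 1.0 + 0.05 * rng.uniform(-1, 1, size=3)
    img = np.clip(field[None] * tints[:, None, None], 0.0, 1.0)
    return img.astype(np.float32)


def _blobs(h, w, rng):
    # pink-ish textured background (eosin-like) with darker purple nuclei
    bg = np.array([0.91, 0.78, 0.86], np.float32)
    tex = gaussian_filter(rng.standard_normal((h, w)), sigma=1.5, mode="reflect")
    tex = 0.04 * tex / max(np.abs(tex).max(), 1e-9)
    img = bg[:, None, None] + tex[None]

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    n_blobs = max(3, int(rng.integers(4, 9)) * (h * w) // (64 * 64))
    nucleus = np.array([0.42, 0.27, 0.55], np.float32)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(4, h - 4), rng.uniform(4, w - 4)
        a = rng.uniform(3.0, 6.5)  # semi-major axis, pixels
        b = a * rng.uniform(0.5, 1.0)  # eccentricity via axis ratio
        th = rng.uniform(0, np.pi)
        ct, st = np.cos(th), np.sin(th)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        d2 = (u / a) ** 2 + (v / b) ** 2
        soft = np.clip(1.2 - d2, 0.0, 1.0)  # soft rim
        shade = nucleus * rng.uniform(0.85, 1.15)
        img = img * (1 - soft[None]) + shade[:, None, None] * soft[None]
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def make_hr_image(spec: FixtureSpec) -> np.ndarray:
    """Render one (3, H, W) float32 HR image in [0, 1] from a spec."""
    spec.validate()
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gradient":
        img = _gradient(h, w, rng)
    elif spec.kind == "checkerboard":
        img = _checkerboard(h, w, rng, spec.block)
    elif spec.kind == "texture":
        img = _texture(h, w, rng)
    else:
        img = _blobs(h, w, rng)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape).astype(np.float32)
        img = np.clip(img, 0.0, 1.0)
    return img.astype(np.float32)


def default_specs(n: int, size=(64, 64), seed: int = 0, noise_sigma: float = 0.0,
                  kinds=KINDS) -> list[FixtureSpec]:
    """A balanced mixture of fixture kinds with per-image seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(FixtureSpec(
            kind=kinds[i % len(kinds)],
            size=tuple(size),
            seed=int(rng.integers(0, 2**31 - 1)),
            noise_sigma=noise_sigma,
        ))
    return out


def make_dataset(n: int, specs, degradation, scale: int, pool=None, seed: int = 0):
    """Generate ``n`` paired (lr, hr) images, degrading HR via the degradation
    module; specs are used cyclically.  lr dims = hr dims / scale."""
    if n < 1:
        raise ValueError("n must be >= 1")
    degradation = replace(degradation, scale=scale)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD47A]))
    pairs = []
    for i in range(n):
        spec = specs[i % len(specs)]
        hr = make_hr_image(spec)
        if hr.shape[1] % scale or hr.shape[2] % scale:
            raise ValueError(f"hr size {hr.shape[1:]} not divisible by scale {scale}")
        lr = degrade(hr, degradation, pool=pool, rng=rng)
        pairs.append((lr, hr))
    return pairs


def split_dataset(items, train_frac: float = 0.8, seed: int = 0):
    """Deterministic shuffled train/test split (default 80/20)."""
    idx = np.random.default_rng(seed).permutation(len(items))
    k = int(round(train_frac * len(items)))
    return [items[i] for i in idx[:k]], [items[i] for i in idx[k:]]
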