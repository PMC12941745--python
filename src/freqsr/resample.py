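"""Shared fixed resamplers (no learned parameters).

One bicubic implementation is used everywhere a bicubic appears — the
generator's global skip, the spatial-consistency reference upsampling, and
the baseline the trained model is compared against — so comparisons never
mix two different interpolants.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import zoom

__all__ = ["bicubic"]


def bicubic(img: np.ndarray, factor: float) -> np.ndarray:
    """Bicubic resampling of a (C, H, W) image by ``factor`` (up or down),
    pixel-area aligned (grid_mode), reflective boundaries."""
    out = [zoom(ch, factor, order=3, mode="reflect", grid_mode=True) for ch in img]
    return np.stack(out).astype(np.float32)
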