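"""Image reading/writing and structured logging.

The package-wide image currency is a channel-first float array in [0, 1]
("ImageTensor"): shape (3, H, W), float32.  Loaders divide by the bit-depth
maximum and replicate grayscale to three channels, so every downstream module
can assume RGB in [0, 1].
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "get_logger", "as_image", "ImageFormatError"]


class ImageFormatError(ValueError):
    pass


def as_image(arr: np.ndarray) -> np.ndarray:
    """Validate/coerce an array to a (3, H, W) float32 image in [0, 1]."""
    a = np.asarray(arr, dtype=np.float32)
    if a.ndim == 2:
        a = a[None]
    if a.ndim != 3 or a.shape[0] not in (1, 3):
        raise ImageFormatError(f"expected (C,H,W) with C in {{1,3}}, got {a.shape}")
    if a.shape[0] == 1:
        a = np.repeat(a, 3, axis=0)
    if not np.isfinite(a).all():
        raise ImageFormatError("image contains non-finite values")
    if a.min() < 0.0 or a.max() > 1.0:
        raise ImageFormatError("image values outside [0, 1]")
    return a


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a (3, H, W) float32 array in [0, 1].

    8-bit values are divided by 255, 16-bit by 65535.  Grayscale inputs are
    replicated to three channels; an alpha channel is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"unreadable image file {path}: {exc}") from exc
    if raw.dtype == np.uint8:
        maxv = 255.0
    elif raw.dtype == np.uint16:
        maxv = 65535.0
    else:
        raise ImageFormatError(f"{path}: unsupported dtype {raw.dtype} (need 8- or 16-bit)")
    if raw.ndim == 2:
        raw = raw[:, :, None]
    if raw.ndim != 3 or raw.shape[2] not in (1, 3):
        raise ImageFormatError(f"{path}: unsupported channel count {raw.shape}")
    img = raw.astype(np.float32).transpose(2, 0, 1) / np.float32(maxv)
    if img.shape[0] == 1:
        img = np.repeat(img, 3, axis=0)
    return img


def write_image(img: np.ndarray, path, bit_depth: int = 8) -> None:
    """Quantize a [0,1] channel-first image to ``bit_depth`` and write PNG/TIFF.

    Values are mapped with round-half-up: stored = floor(v * (2^b - 1) + 0.5).
    Out-of-range values raise; callers clip explicitly if that is intended.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[0] not in (1, 3):
        raise ImageFormatError(f"expected (C,H,W) image, got shape {img.shape}")
    if not np.isfinite(img).all() or img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("write_image requires values in [0, 1]; clip before writing")
    if bit_depth == 8:
        dtype, maxv = np.uint8, 255
    elif bit_depth == 16:
        dtype, maxv = np.uint16, 65535
        if str(path).lower().endswith(".png"):
            raise ImageFormatError(
                "16-bit RGB PNG is not supported by the installed PNG codec; "
                "write 16-bit images as TIFF"
            )
    else:
        raise ValueError("bit_depth must be 8 or 16")
    q = np.floor(img * maxv + 0.5).astype(dtype)
    iio.imwrite(Path(path), q.transpose(1, 2, 0))


_HANDLERS: dict[str, logging.Logger] = {}


def get_logger(name: str, logfile=None) -> logging.Logger:
    """Structured logger: ``timestamp module message`` to stderr (+ optional file)."""
    key = f"freqsr.{name}"
    logger = logging.getLogger(key)
    if key not in _HANDLERS:
        logger.setLevel(logging.INFO)
        fmt = logging.Formatter("%(asctime)s %(name)s %(message)s")
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(fmt)
        logger.addHandler(h)
        if logfile is not None:
            fh = logging.FileHandler(logfile)
            fh.setFormatter(fmt)
            logger.addHandler(fh)
        logger.propagate = False
        _HANDLERS[key] = logger
    return logger
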