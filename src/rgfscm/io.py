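"""Grayscale image I/O (PNG/TIFF, 8- or 16-bit).

Images are normalised to [0, 1] floats on read (dividing by the nominal
maximum of the bit depth) and requantised on write, so a write/read
round-trip is exact up to half a gray level of the target depth.
Multi-channel inputs are converted to a single channel by averaging the
colour channels (luminance average) with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .grid import as_image

__all__ = ["ImageIOError", "read_image", "write_image"]


class ImageIOError(OSError):
    """Raised when an image file cannot be read or written."""


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as a float64 array on [0, 1]."""
    path = Path(path)
    if not path.is_file():
        raise ImageIOError(f"no such image file: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of types for bad files
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        warnings.warn(
            f"{path.name}: multi-channel image; converting by luminance average",
            stacklevel=2,
        )
        arr = arr[..., :3].mean(axis=-1) if arr.shape[-1] >= 3 else arr.mean(axis=-1)
    if arr.ndim != 2 or arr.size == 0:
        raise ImageIOError(f"{path}: expected a non-empty 2-D grayscale image, got shape {arr.shape}")
    if raw.dtype == np.uint8:
        scale = 255.0
    elif raw.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        scale = 1.0  # assume already normalised
    else:
        raise ImageIOError(f"{path}: unsupported pixel type {raw.dtype}")
    img = arr.astype(np.float64) / scale
    return np.clip(img, 0.0, 1.0)


def write_image(image, path, bit_depth: int = 8) -> None:
    """Write a [0, 1] grid as an 8- or 16-bit grayscale PNG/TIFF."""
    img = as_image(image)
    if bit_depth == 8:
        dtype, peak = np.uint8, 255.0
    elif bit_depth == 16:
        dtype, peak = np.uint16, 65535.0
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    quantised = np.round(np.clip(img, 0.0, 1.0) * peak).astype(dtype)
    try:
        iio.imwrite(Path(path), quantised)
    except Exception as exc:
        raise ImageIOError(f"cannot write image {path}: {exc}") from exc
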