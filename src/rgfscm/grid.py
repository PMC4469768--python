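"""Image-grid conventions and validation helpers.

Throughout the package an image is a plain 2-D :class:`numpy.ndarray` of
``float64`` intensities on the nominal range ``[0, 1]`` (8- and 16-bit files
are rescaled on read, see :mod:`rgfscm.io`).  These helpers centralise the
contracts every public operation assumes: finite values, at least one pixel,
and — where two images interact — identical height and width.
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_image", "check_compatible", "check_unit_range"]


def as_image(data, name: str = "image") -> np.ndarray:
    """Coerce *data* to a validated 2-D float64 array.

    Raises
    ------
    ValueError
        If the array is not two-dimensional, is empty, or contains
        non-finite values (NaN/Inf).
    """
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must have at least one pixel, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def check_compatible(a: np.ndarray, b: np.ndarray, names: str = "images") -> None:
    """Two grids are compatible iff they have identical height and width."""
    if a.shape != b.shape:
        raise ValueError(f"incompatible {names}: shapes {a.shape} vs {b.shape}")


def check_unit_range(arr: np.ndarray, name: str = "image", atol: float = 1e-9) -> None:
    """Require intensities on the nominal [0, 1] range (small tolerance)."""
    lo, hi = float(arr.min()), float(arr.max())
    if lo < -atol or hi > 1.0 + atol:
        raise ValueError(
            f"{name} must lie in [0, 1]; observed range [{lo:.6g}, {hi:.6g}]. "
            "Rescale 8/16-bit inputs by their nominal maximum first."
        )
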