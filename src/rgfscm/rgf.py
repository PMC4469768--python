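"""Rolling guidance filter (RGF).

The rolling guidance filter separates image structure by spatial scale: a
Gaussian pass removes structures smaller than ``sigma_s``, then repeated
joint bilateral passes restore the large-scale edges, using the evolving
iterate as the guide image while always averaging the original input.
The iteration converges quickly (a handful of passes suffice) and the
result preserves large edges sharply while small texture stays smoothed —
which is what makes the filtered coefficients a useful saliency signal for
fusion.

Conventions
-----------
* Filter windows are square, of half-width ``window_radius``; by default the
  radius is ``ceil(3 * sigma_s)`` so the window covers ≥99.7 % of the
  Gaussian mass.
* At image borders the window is truncated and the normaliser recomputed
  over in-bounds pixels only (no padding).  This keeps constant images exact
  fixpoints of every filter in this module.
* ``sigma_r`` is expressed in normalised intensity units, so inputs are
  expected on the [0, 1] range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import as_image, check_compatible

__all__ = ["RGFParams", "gaussian_smooth", "joint_bilateral", "rolling_guidance"]


@dataclass
class RGFParams:
    """Parameters of the rolling guidance filter.

    Attributes
    ----------
    sigma_s : float
        Spatial standard deviation in pixels; structures smaller than this
        scale are removed.  Must be positive.
    sigma_r : float
        Range standard deviation in normalised intensity units; controls how
        strongly the bilateral pass respects guide-image edges.
    iterations : int
        Number of joint-bilateral edge-recovery passes performed after the
        initial Gaussian pass (≥ 1).
    window_radius : int or None
        Half-width of the square filter window in pixels.  ``None`` resolves
        to ``ceil(3 * sigma_s)``.
    count_gaussian_pass : bool
        If True, the initial Gaussian pass counts as the first iteration,
        i.e. only ``iterations - 1`` bilateral passes are run.  Off by
        default: "iterations" means bilateral passes.
    """

    sigma_s: float = 1.2
    sigma_r: float = 0.05
    iterations: int = 4
    window_radius: int | None = None
    count_gaussian_pass: bool = False

    def __post_init__(self) -> None:
        if self.sigma_s <= 0:
            raise ValueError(f"sigma_s must be > 0, got {self.sigma_s}")
        if self.sigma_r <= 0:
            raise ValueError(f"sigma_r must be > 0, got {self.sigma_r}")
        if int(self.iterations) != self.iterations or self.iterations < 1:
            raise ValueError(f"iterations must be a positive integer, got {self.iterations}")
        if self.window_radius is not None and (
            int(self.window_radius) != self.window_radius or self.window_radius < 1
        ):
            raise ValueError(f"window_radius must be a positive integer, got {self.window_radius}")

    @property
    def radius(self) -> int:
        """Effective window half-width (resolves the ``None`` default)."""
        if self.window_radius is not None:
            return int(self.window_radius)
        return max(1, math.ceil(3.0 * self.sigma_s))


def _resolve_radius(sigma_s: float, window_radius: int | None) -> int:
    if window_radius is None:
        return max(1, math.ceil(3.0 * sigma_s))
    if int(window_radius) != window_radius or window_radius < 1:
        raise ValueError(f"window_radius must be a positive integer, got {window_radius}")
    return int(window_radius)


def _spatial_kernel(sigma_s: float, radius: int) -> np.ndarray:
    # unnormalised Gaussian; normalisation happens per pixel over the
    # in-bounds window
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    return np.exp(-d2 / (2.0 * sigma_s**2))


def gaussian_smooth(image, sigma_s: float, window_radius: int | None = None) -> np.ndarray:
    """Windowed Gaussian smoothing with border renormalisation.

    Each output pixel is the Gaussian-weighted average of the input over the
    square window centred on it; weights are renormalised over the in-bounds
    part of the window, so constant images are reproduced exactly.
    """
    img = as_image(image)
    if sigma_s <= 0:
        raise ValueError(f"sigma_s must be > 0, got {sigma_s}")
    radius = _resolve_radius(sigma_s, window_radius)
    kernel = _spatial_kernel(sigma_s, radius)
    # filter the deviation from the mean and add it back: algebraically the
    # same weighted average, but constant images come out bit-exact
    m = img.mean()
    num = ndimage.correlate(img - m, kernel, mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones_like(img), kernel, mode="constant", cval=0.0)
    return m + num / den


def joint_bilateral(input_image, guide, params: RGFParams) -> np.ndarray:
    """Joint (cross) bilateral filter.

    Spatial weights come from pixel distance; range weights come from
    intensity differences of the *guide* image; the values averaged are those
    of *input_image*.  With a spatially constant guide the range weights are
    all equal and the filter reduces exactly to :func:`gaussian_smooth`.
    """
    img = as_image(input_image, "input")
    jt = as_image(guide, "guide")
    check_compatible(img, jt)
    radius = params.radius
    inv_2ss = 1.0 / (2.0 * params.sigma_s**2)
    inv_2sr = 1.0 / (2.0 * params.sigma_r**2)

    h, w = img.shape
    m = img.mean()  # same mean-deviation trick as gaussian_smooth
    dev = img - m
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    # accumulate one window offset at a time; out-of-bounds neighbours are
    # simply never visited, which implements window truncation
    for dy in range(-radius, radius + 1):
        y0d, y1d = max(0, -dy), h - max(0, dy)  # centre-pixel rows
        if y0d >= y1d:
            continue
        y0s, y1s = max(0, dy), h - max(0, -dy)  # neighbour rows
        for dx in range(-radius, radius + 1):
            x0d, x1d = max(0, -dx), w - max(0, dx)
            if x0d >= x1d:
                continue
            x0s, x1s = max(0, dx), w - max(0, -dx)
            ws = math.exp(-(dy * dy + dx * dx) * inv_2ss)
            diff = jt[y0d:y1d, x0d:x1d] - jt[y0s:y1s, x0s:x1s]
            wgt = ws * np.exp(-(diff * diff) * inv_2sr)
            num[y0d:y1d, x0d:x1d] += wgt * dev[y0s:y1s, x0s:x1s]
            den[y0d:y1d, x0d:x1d] += wgt
    return m + num / den


def rolling_guidance(image, params: RGFParams | None = None) -> np.ndarray:
    """Full rolling guidance filter: Gaussian pass, then iterative recovery.

    The first iterate is the Gaussian-smoothed input (equivalently a joint
    bilateral pass guided by a constant image); each subsequent iterate is a
    joint bilateral pass whose guide is the previous iterate and whose
    averaged values come from the original input.
    """
    params = params or RGFParams()
    img = as_image(image)
    n_bilateral = params.iterations - (1 if params.count_gaussian_pass else 0)
    j = gaussian_smooth(img, params.sigma_s, params.radius)
    for _ in range(n_bilateral):
        j = joint_bilateral(img, j, params)
    return j
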