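"""Synthetic phantom pairs for testing and demos.

No clinical data ships with this package, so a deterministic phantom
generator stands in for real multimodal pairs.  It emulates the qualitative
premise of CT/MR-style fusion inputs: the two modalities are co-registered
but carry *complementary* content —

* image A ("bone-like"): a bright elliptical rim (skull) and a few compact
  high-intensity inclusions over a dark, nearly featureless interior;
* image B ("soft-tissue-like"): smooth low-frequency blobs inside the rim
  plus fine-grained texture well below ``structure_scale``, with the rim
  itself dark.

This gives the scale-separating rolling guidance filter something real to
act on (fine texture to remove, large structures to keep), and the fusion
rule genuinely different saliency in the two sources.  It is synthetic:
intensity statistics, noise character and anatomy of real scanners are not
modelled, so results on phantoms demonstrate mechanism, not clinical
performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import as_image, check_unit_range

__all__ = ["PhantomSpec", "make_phantom_pair", "add_gaussian_noise"]


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic phantom pair.

    ``structure_scale`` is the characteristic size (pixels) of the blobs in
    the soft-tissue image; the fine texture lives at roughly one eighth of
    it.  ``contrast`` scales every structure above the background (0 gives
    two constant images); ``texture_amplitude`` sets the fine-texture
    standard deviation before contrast scaling.
    """

    height: int = 128
    width: int = 128
    structure_scale: float = 16.0
    contrast: float = 0.9
    texture_amplitude: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom must be at least 16x16")
        if self.structure_scale < 1:
            raise ValueError("structure_scale must be >= 1")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")


def _ellipse_dist(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)


def make_phantom_pair(spec: PhantomSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Generate a registered complementary pair; deterministic given seed."""
    spec = spec or PhantomSpec()
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.46 * h, 0.46 * w
    d = _ellipse_dist(h, w, cy, cx, ry, rx)
    interior = d < 0.82
    rim = (d >= 0.82) & (d <= 1.0)

    # --- image A: bone-like ---
    a = np.full((h, w), 0.05)
    a[rim] += spec.contrast * 0.9
    a[interior] += spec.contrast * 0.12
    # a few compact bright inclusions (calcification-like)
    for _ in range(3):
        icy = cy + rng.uniform(-0.4, 0.4) * ry
        icx = cx + rng.uniform(-0.4, 0.4) * rx
        r = rng.uniform(0.1, 0.25) * spec.structure_scale + 2.0
        blob = _ellipse_dist(h, w, icy, icx, r, r) < 1.0
        a[blob & interior] = 0.05 + spec.contrast * 0.95

    # --- image B: soft-tissue-like ---
    b = np.full((h, w), 0.10)
    tissue = np.zeros((h, w))
    for _ in range(5):
        bcy = cy + rng.uniform(-0.5, 0.5) * ry
        bcx = cx + rng.uniform(-0.5, 0.5) * rx
        s = rng.uniform(0.6, 1.4) * spec.structure_scale
        yy, xx = np.mgrid[0:h, 0:w]
        tissue += rng.uniform(0.4, 1.0) * np.exp(
            -(((yy - bcy) ** 2 + (xx - bcx) ** 2) / (2.0 * s * s))
        )
    if tissue.max() > 0:
        tissue /= tissue.max()
    texture = ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=max(0.5, spec.structure_scale / 8.0)
    )
    t_std = texture.std()
    if t_std > 0:
        texture *= spec.texture_amplitude / t_std
    b[interior] += spec.contrast * (0.55 * tissue[interior] + texture[interior])

    return np.clip(a, 0.0, 1.0), np.clip(b, 0.0, 1.0)


def add_gaussian_noise(image, sigma_gray_levels: float, seed: int) -> np.ndarray:
    """Add zero-mean Gaussian noise, sigma expressed in 8-bit gray levels.

    The noise standard deviation on the normalised image is
    ``sigma_gray_levels / 255``; the result is clipped back to [0, 1]
    (the only place the pipeline clips).  Deterministic given seed;
    ``sigma_gray_levels = 0`` returns the input unchanged.
    """
    img = as_image(image)
    check_unit_range(img)
    if sigma_gray_levels < 0:
        raise ValueError("sigma_gray_levels must be >= 0")
    if sigma_gray_levels == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    noisy = img + rng.normal(0.0, sigma_gray_levels / 255.0, size=img.shape)
    return np.clip(noisy, 0.0, 1.0)
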