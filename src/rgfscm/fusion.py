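"""Pairwise fusion pipeline: RGF saliency → dual SCM runs → count rule.

Given two co-registered grayscale sources A and B on [0, 1]:

1. Rolling guidance filtering extracts the large-scale structure (saliency)
   of each source: ``A_RGF = RGF(A)``, ``B_RGF = RGF(B)``.
2. The RGF coefficient maps are min–max normalised and fed as stimuli to two
   spiking cortical models sharing the same parameters; unless overridden,
   the threshold magnitude h is derived adaptively from the *source* images.
   Each run yields a per-pixel firing-count map (T_A, T_B).
3. Per pixel, with count difference d = T_A − T_B and constant threshold
   T_th (default 1):

   * d > T_th   → take A's pixel,
   * d = T_th   → average the two pixels,
   * otherwise  → take B's pixel.

The default rule is *signed*, exactly as stated above: it is asymmetric and
favours B on ties and negative differences, so swapping the inputs can
change the output.  A symmetric variant (decide on \\|d\\| and average inside
the band \\|d\\| ≤ T_th) is available via ``decision="symmetric"``.

Fire counts are integers, so with the default T_th = 1 the equality branch
is well-posed; a non-integer T_th simply leaves it empty (exact comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .grid import as_image, check_compatible, check_unit_range
from .rgf import RGFParams, rolling_guidance
from .scm import DEFAULT_LINKING_KERNEL, SCMParams, adaptive_h, scm_fire_counts

__all__ = [
    "FusionConfig",
    "normalize_coefficients",
    "decision_map",
    "fuse_pair",
    "run_ablation",
    "ABLATION_VARIANTS",
]

#: Ablation variants: which stimulus feeds the SCMs and how h is chosen.
#: All variants share the same per-pixel count decision rule.
ABLATION_VARIANTS = ("SCM", "SCM-A", "RGF-SCM-C", "RGF-SCM")


@dataclass
class FusionConfig:
    """Everything needed to run the fusion pipeline.

    Attributes
    ----------
    rgf : RGFParams
        Rolling-guidance-filter parameters.
    scm : SCMParams
        Spiking-cortical-model parameters; ``scm.h = None`` means the
        threshold magnitude is computed adaptively from the sources.
    t_threshold : float
        Constant decision threshold T_th on the firing-count difference
        (≥ 0; default 1).
    decision : str
        ``"signed"`` (default, the rule as stated in the module docstring)
        or ``"symmetric"``.
    h_variant : str
        Reading of the adaptive-h formula, passed to
        :func:`rgfscm.scm.adaptive_h`.  The default computes the source
        statistics on the 8-bit gray-level scale, which keeps the threshold
        recoil commensurate with the accumulated internal activity (see
        :func:`rgfscm.scm.adaptive_h`); ``"average"`` and ``"sum"`` are the
        [0, 1]-scale readings.
    constant_h : float
        Threshold magnitude used by the constant-h ablation variants
        (``SCM`` and ``RGF-SCM-C``); defaults to 20, the classical choice
        for this model with unit-range stimuli.
    """

    rgf: RGFParams = field(default_factory=RGFParams)
    scm: SCMParams = field(default_factory=SCMParams)
    t_threshold: float = 1.0
    decision: str = "signed"
    h_variant: str = "average_gray"
    constant_h: float = 20.0

    def __post_init__(self) -> None:
        if self.t_threshold < 0:
            raise ValueError(f"t_threshold must be >= 0, got {self.t_threshold}")
        if self.decision not in ("signed", "symmetric"):
            raise ValueError(f"unknown decision rule {self.decision!r}")

    def to_dict(self) -> dict[str, Any]:
        """Flat key-value form, suitable for JSON/YAML serialisation."""
        return {
            "sigma_s": self.rgf.sigma_s,
            "sigma_r": self.rgf.sigma_r,
            "rgf_iterations": self.rgf.iterations,
            "window_radius": self.rgf.window_radius,
            "count_gaussian_pass": self.rgf.count_gaussian_pass,
            "f": self.scm.f,
            "g": self.scm.g,
            "h": "adaptive" if self.scm.h is None else self.scm.h,
            "W": np.asarray(self.scm.W).tolist(),
            "n_iters": self.scm.n_iters,
            "firing_rule": self.scm.firing_rule,
            "t_threshold": self.t_threshold,
            "decision": self.decision,
            "h_variant": self.h_variant,
            "constant_h": self.constant_h,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FusionConfig":
        """Build a config from the flat key-value form; missing keys default."""
        d = dict(d)
        h = d.get("h", "adaptive")
        rgf = RGFParams(
            sigma_s=d.get("sigma_s", 1.2),
            sigma_r=d.get("sigma_r", 0.05),
            iterations=d.get("rgf_iterations", 4),
            window_radius=d.get("window_radius"),
            count_gaussian_pass=d.get("count_gaussian_pass", False),
        )
        scm = SCMParams(
            f=d.get("f", 0.8),
            g=d.get("g", 0.7),
            h=None if h == "adaptive" else float(h),
            W=np.asarray(d["W"]) if "W" in d else DEFAULT_LINKING_KERNEL.copy(),
            n_iters=d.get("n_iters", 40),
            firing_rule=d.get("firing_rule", "standard"),
        )
        return cls(
            rgf=rgf,
            scm=scm,
            t_threshold=d.get("t_threshold", 1.0),
            decision=d.get("decision", "signed"),
            h_variant=d.get("h_variant", "average_gray"),
            constant_h=d.get("constant_h", 20.0),
        )


def normalize_coefficients(image) -> np.ndarray:
    """Affine min–max rescaling to [0, 1].

    A perfectly flat image maps to all 0.5: any constant would do as a
    stimulus, and the midpoint avoids both the never-fire (0) and the
    saturated (1) extremes.
    """
    img = as_image(image)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.full_like(img, 0.5)
    return (img - lo) / (hi - lo)


def decision_map(t_a: np.ndarray, t_b: np.ndarray, t_threshold: float = 1.0,
                 decision: str = "signed") -> np.ndarray:
    """Per-pixel fusion decision from two firing-count maps.

    Returns an int8 map with 0 where A's pixel is taken, 1 where the two
    pixels are averaged, and 2 where B's pixel is taken.  The three masks
    are disjoint and cover every pixel by construction.
    """
    t_a = np.asarray(t_a)
    t_b = np.asarray(t_b)
    check_compatible(t_a, t_b, "fire-count maps")
    d = t_a.astype(np.float64) - t_b.astype(np.float64)
    out = np.full(d.shape, 2, dtype=np.int8)  # default branch: B
    if decision == "signed":
        out[d == t_threshold] = 1
        out[d > t_threshold] = 0
    elif decision == "symmetric":
        out[np.abs(d) <= t_threshold] = 1
        out[d > t_threshold] = 0
    else:
        raise ValueError(f"unknown decision rule {decision!r}")
    return out


def _compose(a: np.ndarray, b: np.ndarray, decisions: np.ndarray) -> np.ndarray:
    return np.where(decisions == 0, a, np.where(decisions == 1, (a + b) / 2.0, b))


def _fuse_with_stimuli(a, b, stim_a, stim_b, scm_params, config):
    t_a = scm_fire_counts(stim_a, scm_params).counts
    t_b = scm_fire_counts(stim_b, scm_params).counts
    decisions = decision_map(t_a, t_b, config.t_threshold, config.decision)
    return _compose(a, b, decisions)


def fuse_pair(a, b, config: FusionConfig | None = None) -> np.ndarray:
    """Fuse two co-registered, same-size sources on [0, 1].

    Registration is the caller's responsibility; the pipeline only checks
    shape compatibility.  The output is a per-pixel selection (or average)
    of the two source pixels, hence also on [0, 1].
    """
    config = config or FusionConfig()
    a = as_image(a, "A")
    b = as_image(b, "B")
    check_compatible(a, b)
    check_unit_range(a, "A")
    check_unit_range(b, "B")
    a_rgf = rolling_guidance(a, config.rgf)
    b_rgf = rolling_guidance(b, config.rgf)
    scm_params = config.scm.resolved([a, b], config.h_variant)
    return _fuse_with_stimuli(
        a, b,
        normalize_coefficients(a_rgf),
        normalize_coefficients(b_rgf),
        scm_params, config,
    )


def run_ablation(a, b, variant: str, config: FusionConfig | None = None) -> np.ndarray:
    """Run one of the pipeline ablations; all share the count decision rule.

    ========== ======================== =======================
    variant    SCM stimulus             threshold magnitude h
    ========== ======================== =======================
    SCM        normalised raw images    constant (``constant_h``)
    SCM-A      normalised raw images    adaptive
    RGF-SCM-C  normalised RGF outputs   constant (``constant_h``)
    RGF-SCM    normalised RGF outputs   adaptive (the full method)
    ========== ======================== =======================
    """
    config = config or FusionConfig()
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {ABLATION_VARIANTS}")
    if variant == "RGF-SCM":
        return fuse_pair(a, b, config)
    a = as_image(a, "A")
    b = as_image(b, "B")
    check_compatible(a, b)
    check_unit_range(a, "A")
    check_unit_range(b, "B")
    if variant in ("SCM", "SCM-A"):
        stim_a, stim_b = normalize_coefficients(a), normalize_coefficients(b)
    else:  # RGF-SCM-C
        stim_a = normalize_coefficients(rolling_guidance(a, config.rgf))
        stim_b = normalize_coefficients(rolling_guidance(b, config.rgf))
    if variant in ("SCM", "RGF-SCM-C"):
        scm_params = replace(config.scm, h=config.constant_h)
    else:  # SCM-A
        scm_params = replace(config.scm, h=adaptive_h([a, b], config.h_variant))
    return _fuse_with_stimuli(a, b, stim_a, stim_b, scm_params, config)
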