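"""Spiking cortical model (SCM).

A simplified pulse-coupled neural network: one neuron per pixel integrates
its external stimulus S and the pulses of its 8-neighbours into an internal
activity U, and fires against a dynamic threshold E that recoils by the
threshold magnitude h after each firing and decays geometrically otherwise.

Per iteration n (from the rest state U = E = Y = T = 0):

.. math::

    U(n) &= f\\,U(n-1) + S \\odot (W \\circledast Y(n-1)) + S \\\\
    E(n) &= g\\,E(n-1) + h\\,Y(n-1) \\\\
    Y(n) &= [U(n) > E(n)] \\\\
    T(n) &= T(n-1) + Y(n)

where ``W`` is the 3×3 linking kernel (correlation, zero center — a neuron
does not link to itself; missing neighbours beyond the border contribute
nothing) and ``T`` accumulates the per-pixel firing count, the saliency
measure used by the fusion rule.

The firing condition deserves a note.  Writing the pulse generator as a
sigmoid of the activity/threshold difference, the convention used here fires
when ``U > E`` (sigmoid with negative exponent above one half).  The
opposite sign convention — fire when ``U < E`` — also circulates in print,
but under it a rested network with positive stimulus never fires and every
fire count is zero, which collapses any count-based fusion rule; it is kept
available as ``firing_rule="inverted"`` for fidelity experiments only.

The threshold magnitude h may be a fixed constant, or derived from the
source-image statistics via :func:`adaptive_h`, which makes the model
self-scaling across modalities with different brightness distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .grid import as_image, check_compatible, check_unit_range

__all__ = [
    "DEFAULT_LINKING_KERNEL",
    "SCMParams",
    "SCMState",
    "FireCountMap",
    "adaptive_h",
    "scm_step",
    "scm_fire_counts",
]

#: Default 3×3 synaptic linking kernel: inverse-distance-flavoured weights
#: to the 8-neighbours, zero self-link.
DEFAULT_LINKING_KERNEL = np.array(
    [
        [0.1091, 0.1409, 0.1091],
        [0.1409, 0.0, 0.1409],
        [0.1091, 0.1409, 0.1091],
    ]
)


def _default_kernel() -> np.ndarray:
    return DEFAULT_LINKING_KERNEL.copy()


@dataclass
class SCMParams:
    """Parameters of the spiking cortical model.

    Attributes
    ----------
    f : float
        Attenuation of the internal activity U per iteration, in (0, 1).
    g : float
        Attenuation of the dynamic threshold E per iteration, in (0, 1).
    h : float or None
        Threshold magnitude added to E after a neuron fires, in normalised
        intensity units.  ``None`` means "adaptive": resolve from the source
        images with :func:`adaptive_h` before running (the fusion pipeline
        does this automatically).
    W : ndarray
        3×3 nonnegative linking kernel with zero centre.
    n_iters : int
        Number of iterations to run (≥ 1).
    firing_rule : str
        ``"standard"`` fires when U > E; ``"inverted"`` fires when U < E
        (see module docstring).
    """

    f: float = 0.8
    g: float = 0.7
    h: float | None = None
    W: np.ndarray = field(default_factory=_default_kernel)
    n_iters: int = 40
    firing_rule: str = "standard"

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"f must lie in (0, 1), got {self.f}")
        if not 0.0 < self.g < 1.0:
            raise ValueError(f"g must lie in (0, 1), got {self.g}")
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.shape != (3, 3):
            raise ValueError(f"W must be 3x3, got shape {self.W.shape}")
        if np.any(self.W < 0):
            raise ValueError("W must be nonnegative")
        if self.W[1, 1] != 0:
            raise ValueError("W must have zero centre (no self-linking)")
        if int(self.n_iters) != self.n_iters or self.n_iters < 1:
            raise ValueError(f"n_iters must be a positive integer, got {self.n_iters}")
        if self.firing_rule not in ("standard", "inverted"):
            raise ValueError(f"unknown firing_rule {self.firing_rule!r}")

    def resolved(self, sources: Sequence[np.ndarray], h_variant: str = "average_gray") -> "SCMParams":
        """Return a copy with ``h`` resolved (adaptive if it was ``None``)."""
        if self.h is not None:
            return self
        return replace(self, h=adaptive_h(sources, variant=h_variant))


@dataclass
class SCMState:
    """Full state of an SCM run after ``step`` iterations."""

    U: np.ndarray
    E: np.ndarray
    Y: np.ndarray
    T: np.ndarray
    step: int = 0

    @classmethod
    def rest(cls, shape: tuple[int, int]) -> "SCMState":
        """The rest state: zero activity, threshold, pulses and counts."""
        return cls(
            U=np.zeros(shape),
            E=np.zeros(shape),
            Y=np.zeros(shape),
            T=np.zeros(shape, dtype=np.int64),
            step=0,
        )


class FireCountMap(NamedTuple):
    """Per-pixel total firing counts T over an n_iters-iteration run."""

    counts: np.ndarray
    n_iters: int


def adaptive_h(sources: Sequence[np.ndarray], variant: str = "average") -> float:
    """Self-adaptive threshold magnitude from source-image statistics.

    With ``variant="average"`` (default),

    .. math:: h = \\frac{1}{m}\\sum_i \\mathrm{mean}(I_i)
                 - \\frac{1}{3}\\,\\frac{1}{m}\\sum_i \\mathrm{std}(I_i),

    the average of the per-image mean intensities minus one third of the
    average per-image (population) standard deviation, computed on [0, 1]
    intensities.  ``variant="sum"`` omits the 1/m factors (the two readings
    differ only by the scale m).  Brighter, flatter sources thus raise the
    threshold; busy, high-variance sources lower it.

    ``variant="average_gray"`` evaluates the same statistics on the 8-bit
    gray-level scale (i.e. multiplies by 255), which is the variant the
    fusion pipeline uses by default.  The distinction matters: the threshold
    recoil h competes with an internal activity that accumulates to roughly
    ``S/(1-f)`` ≈ 10 for bright stimuli, so an h of a few hundredths (the
    [0, 1] reading) lets nearly every neuron fire on every iteration and the
    fire-count map saturates, carrying no saliency; with h of a few tens
    (the gray-level reading, the magnitude classically used for this model)
    neurons refire with a period set by their stimulus strength and the
    counts grade cleanly with saliency.
    """
    if len(sources) == 0:
        raise ValueError("adaptive_h requires at least one source image")
    if variant not in ("average", "sum", "average_gray"):
        raise ValueError(f"unknown adaptive_h variant {variant!r}")
    imgs = [as_image(s, f"source {i}") for i, s in enumerate(sources)]
    means = [float(im.mean()) for im in imgs]
    stds = [float(im.std()) for im in imgs]  # population std
    m = len(imgs)
    h = sum(means) - sum(stds) / 3.0
    if variant in ("average", "average_gray"):
        h /= m
    if variant == "average_gray":
        h *= 255.0
    return h


def scm_step(state: SCMState, stimulus: np.ndarray, params: SCMParams) -> SCMState:
    """Advance the model by one iteration; returns a new state.

    Update order within the step: the dynamic threshold decays and recoils
    using the *previous* pulses, the internal activity integrates stimulus
    and neighbour pulses, then the new pulses are emitted and counted.
    """
    s = as_image(stimulus, "stimulus")
    check_compatible(s, state.U, "stimulus/state")
    if params.h is None:
        raise ValueError("params.h is unresolved; set a constant or use SCMParams.resolved()")
    link = ndimage.correlate(state.Y, params.W, mode="constant", cval=0.0)
    u = params.f * state.U + s * link + s
    e = params.g * state.E + params.h * state.Y
    if params.firing_rule == "standard":
        y = (u > e).astype(np.float64)
    else:  # inverted sign convention, kept for fidelity experiments
        y = (u < e).astype(np.float64)
    t = state.T + y.astype(np.int64)
    return SCMState(U=u, E=e, Y=y, T=t, step=state.step + 1)


def scm_fire_counts(stimulus: np.ndarray, params: SCMParams) -> FireCountMap:
    """Run the model from rest for ``params.n_iters`` steps; return counts."""
    s = as_image(stimulus, "stimulus")
    check_unit_range(s, "stimulus")
    state = SCMState.rest(s.shape)
    for _ in range(params.n_iters):
        state = scm_step(state, s, params)
    return FireCountMap(counts=state.T, n_iters=params.n_iters)
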