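"""Independent straight-line reference implementations.

Everything here is written as explicit Python loops over pixels, directly
transcribing the defining formulas, and is deliberately kept separate from
the package's vectorised code paths so the two can be compared as
independent routes to the same numbers.  Only usable at small sizes.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_gaussian(img: np.ndarray, sigma_s: float, radius: int) -> np.ndarray:
    """Quadruple-loop windowed Gaussian with border renormalisation."""
    h, w = img.shape
    out = np.zeros((h, w))
    for py in range(h):
        for px in range(w):
            num = 0.0
            k = 0.0
            for qy in range(max(0, py - radius), min(h, py + radius + 1)):
                for qx in range(max(0, px - radius), min(w, px + radius + 1)):
                    d2 = (py - qy) ** 2 + (px - qx) ** 2
                    wgt = math.exp(-d2 / (2.0 * sigma_s**2))
                    num += wgt * img[qy, qx]
                    k += wgt
            out[py, px] = num / k
    return out


def oracle_joint_bilateral(
    img: np.ndarray, guide: np.ndarray, sigma_s: float, sigma_r: float, radius: int
) -> np.ndarray:
    """Quadruple-loop joint bilateral filter: spatial weights from distance,
    range weights from guide differences, averaged values from img."""
    h, w = img.shape
    out = np.zeros((h, w))
    for py in range(h):
        for px in range(w):
            num = 0.0
            k = 0.0
            for qy in range(max(0, py - radius), min(h, py + radius + 1)):
                for qx in range(max(0, px - radius), min(w, px + radius + 1)):
                    d2 = (py - qy) ** 2 + (px - qx) ** 2
                    dr = guide[py, px] - guide[qy, qx]
                    wgt = math.exp(
                        -d2 / (2.0 * sigma_s**2) - dr * dr / (2.0 * sigma_r**2)
                    )
                    num += wgt * img[qy, qx]
                    k += wgt
            out[py, px] = num / k
    return out


def oracle_rolling_guidance(
    img: np.ndarray, sigma_s: float, sigma_r: float, iterations: int, radius: int
) -> np.ndarray:
    j = oracle_gaussian(img, sigma_s, radius)
    for _ in range(iterations):
        j = oracle_joint_bilateral(img, j, sigma_s, sigma_r, radius)
    return j


def oracle_scm_counts(
    stim: np.ndarray,
    f: float,
    g: float,
    h: float,
    W: np.ndarray,
    n_iters: int,
    return_trace: bool = False,
):
    """Explicit-loop iteration of the spiking-cortical-model recurrence."""
    hh, ww = stim.shape
    U = np.zeros((hh, ww))
    E = np.zeros((hh, ww))
    Y = np.zeros((hh, ww))
    T = np.zeros((hh, ww), dtype=np.int64)
    trace = []
    for _ in range(n_iters):
        link = np.zeros((hh, ww))
        for i in range(hh):
            for j in range(ww):
                acc = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if 0 <= ni < hh and 0 <= nj < ww:
                            acc += W[di + 1, dj + 1] * Y[ni, nj]
                link[i, j] = acc
        U_new = np.zeros((hh, ww))
        E_new = np.zeros((hh, ww))
        Y_new = np.zeros((hh, ww))
        for i in range(hh):
            for j in range(ww):
                U_new[i, j] = f * U[i, j] + stim[i, j] * link[i, j] + stim[i, j]
                E_new[i, j] = g * E[i, j] + h * Y[i, j]
                Y_new[i, j] = 1.0 if U_new[i, j] > E_new[i, j] else 0.0
                T[i, j] += int(Y_new[i, j])
        U, E, Y = U_new, E_new, Y_new
        if return_trace:
            trace.append((U.copy(), E.copy(), Y.copy()))
    if return_trace:
        return T, trace
    return T


_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


def oracle_sobel(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Explicit-loop Sobel with symmetric edge padding; returns magnitude
    and orientation folded into [-pi/2, pi/2)."""
    padded = np.pad(img, 1, mode="symmetric")
    h, w = img.shape
    strength = np.zeros((h, w))
    orient = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            sx = 0.0
            sy = 0.0
            for u in range(3):
                for v in range(3):
                    sx += _SOBEL_X[u, v] * padded[i + u, j + v]
                    sy += _SOBEL_Y[u, v] * padded[i + u, j + v]
            strength[i, j] = math.hypot(sx, sy)
            a = math.atan2(sy, sx)
            orient[i, j] = (a + math.pi / 2) % math.pi - math.pi / 2
    return strength, orient


def oracle_mi_pair(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Mutual information in bits via explicitly accumulated joint counts."""
    joint = np.zeros((bins, bins))
    for xi, yi in zip(x.ravel(), y.ravel()):
        bx = min(int(xi * bins), bins - 1)
        by = min(int(yi * bins), bins - 1)
        joint[bx, by] += 1
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if p[i, j] > 0:
                mi += p[i, j] * math.log2(p[i, j] / (px[i] * py[j]))
    return mi


def oracle_petrovic(
    a: np.ndarray,
    b: np.ndarray,
    f: np.ndarray,
    gamma_g=0.9994,
    kappa_g=-15.0,
    sigma_g=0.5,
    gamma_a=0.9879,
    kappa_a=-22.0,
    sigma_a=0.8,
) -> tuple[float, float, float]:
    """Per-pixel loop over the edge-preservation model."""
    g_a, o_a = oracle_sobel(a)
    g_b, o_b = oracle_sobel(b)
    g_f, o_f = oracle_sobel(f)
    h, w = a.shape
    num_q = 0.0
    num_l = 0.0
    num_n = 0.0
    den = 0.0

    def pres(gs, os_, gf, of):
        if gs == 0.0 and gf == 0.0:
            g_rel = 1.0
        elif gs == 0.0 or gf == 0.0:
            g_rel = 0.0
        else:
            g_rel = min(gs, gf) / max(gs, gf)
        a_rel = 1.0 - abs(os_ - of) / (math.pi / 2)
        qg = gamma_g / (1.0 + math.exp(kappa_g * (g_rel - sigma_g)))
        qa = gamma_a / (1.0 + math.exp(kappa_a * (a_rel - sigma_a)))
        return qg * qa

    for i in range(h):
        for j in range(w):
            qaf = pres(g_a[i, j], o_a[i, j], g_f[i, j], o_f[i, j])
            qbf = pres(g_b[i, j], o_b[i, j], g_f[i, j], o_f[i, j])
            wa, wb = g_a[i, j], g_b[i, j]
            den += wa + wb
            num_q += qaf * wa + qbf * wb
            resid = (1.0 - qaf) * wa + (1.0 - qbf) * wb
            if g_f[i, j] > g_a[i, j] and g_f[i, j] > g_b[i, j]:
                num_n += resid
            else:
                num_l += resid
    if den == 0.0:
        return 1.0, 0.0, 0.0
    return num_q / den, num_l / den, num_n / den


def oracle_fuse(
    a: np.ndarray,
    b: np.ndarray,
    sigma_s: float,
    sigma_r: float,
    rgf_iterations: int,
    radius: int,
    f: float,
    g: float,
    W: np.ndarray,
    n_iters: int,
    t_th: float,
) -> np.ndarray:
    """Straight-line composition of the whole pipeline from the oracles:
    rolling guidance, min-max normalisation, adaptive h, dual SCM runs,
    signed count-difference rule."""

    def norm(x):
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.full_like(x, 0.5)
        return (x - lo) / (hi - lo)

    a_rgf = oracle_rolling_guidance(a, sigma_s, sigma_r, rgf_iterations, radius)
    b_rgf = oracle_rolling_guidance(b, sigma_s, sigma_r, rgf_iterations, radius)
    # adaptive threshold magnitude: statistics on the 8-bit gray-level scale
    h_adapt = 255.0 * ((a.mean() + b.mean()) / 2.0 - (a.std() + b.std()) / 6.0)
    t_a = oracle_scm_counts(norm(a_rgf), f, g, h_adapt, W, n_iters)
    t_b = oracle_scm_counts(norm(b_rgf), f, g, h_adapt, W, n_iters)
    out = np.zeros_like(a)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            d = float(t_a[i, j] - t_b[i, j])
            if d > t_th:
                out[i, j] = a[i, j]
            elif d == t_th:
                out[i, j] = (a[i, j] + b[i, j]) / 2.0
            else:
                out[i, j] = b[i, j]
    return out
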