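"""V2-h phase-plane analysis of the spike generator.

Treating the soma voltage V1 as a (slow) input to the axon compartment,
the fast subsystem lives in the (V2, h) plane. The V2-nullcline for a
fixed V1 is the set of (V2, h) where the axon membrane equation balances:

    0 = -g2 (V2 - Elk) - gc (V2 - V1) - I_KLT2(V2) - I_Na(V2, h)

Because h enters I_Na linearly, the nullcline is solved for h in closed
form at each V2. Cubic-shaped nullclines carry a local maximum (the left
knee) whose height against the trajectory's h sets the firing threshold of
the fast subsystem; the knee sinks and vanishes as V1 is depolarized in
strongly forward-coupled models, which is what forbids repetitive firing
there. Fixed points are intersections with the h-nullcline h = h_inf(V2).

When KLT in the axon compartment is dynamic its activation is evaluated at
quasi-steady state w = w_inf(V2); this approximation is used only here,
for diagnostics, not by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import channels as ch
from .params import TwoCompartmentParams

__all__ = ["NullclineCurve", "v2_nullcline", "left_knee", "fixed_points", "h_nullcline"]


@dataclass(frozen=True)
class NullclineCurve:
    """Sampled V2-nullcline at a fixed soma voltage."""

    V2: np.ndarray  # mV
    h: np.ndarray  # gate fraction (clipped to [-0.1, 1.1])
    V1_fixed: float
    branch: np.ndarray  # str labels: left / middle / right

    def __len__(self) -> int:
        return len(self.V2)


def _h_on_nullcline(params: TwoCompartmentParams, V1_fixed: float, V2: np.ndarray) -> np.ndarray:
    """Closed-form h such that the V2 equation balances at (V2, h)."""
    p = params
    Vr = p.Vrest
    z_r = float(ch.z_inf(Vr))
    if p.klt_mode == "dynamic" and p.gKLT2 > 0:
        w2 = np.asarray(ch.w_inf(V2))
    else:
        w2 = float(ch.w_inf(Vr))
    iklt2 = p.gKLT2 * w2**4 * z_r * (V2 - p.EK) - p.gKLT2 * float(ch.w_inf(Vr)) ** 4 * z_r * (
        Vr - p.EK
    )
    ina_rest = p.gNa * float(ch.m_inf(Vr)) ** 3 * float(ch.h_inf(Vr)) * (Vr - p.ENa)
    numer = -p.g2 * (V2 - p.Elk) - p.gc * (V2 - V1_fixed) - iklt2 + ina_rest
    denom = p.gNa * np.asarray(ch.m_inf(V2)) ** 3 * (V2 - p.ENa)
    with np.errstate(divide="ignore", invalid="ignore"):
        return numer / denom


def _label_branches(V2: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Partition the curve at its knees: local max = left knee, local min = right."""
    labels = np.full(len(V2), "left", dtype=object)
    if len(h) < 3:
        return labels
    dh = np.diff(h)
    maxima = np.nonzero((dh[:-1] > 0) & (dh[1:] <= 0))[0] + 1
    minima = np.nonzero((dh[:-1] < 0) & (dh[1:] >= 0))[0] + 1
    v_lk = V2[maxima[0]] if maxima.size else None
    v_rk = V2[minima[0]] if minima.size else None
    if v_lk is not None:
        labels[V2 >= v_lk] = "middle"
    if v_rk is not None:
        labels[V2 >= v_rk] = "right"
    return labels


def v2_nullcline(
    params: TwoCompartmentParams,
    V1_fixed: float,
    v2_range: tuple[float, float] = (-80.0, 60.0),
    dv: float = 0.05,
    h_clip: tuple[float, float] = (-0.1, 1.1),
) -> NullclineCurve:
    """Sample the V2-nullcline for a fixed soma voltage.

    Points are kept where the closed-form h is finite and within
    ``h_clip`` (a margin beyond [0, 1] for plotting); the singular point
    V2 = ENa is excluded.
    """
    if params.gNa <= 0:
        raise ValueError("V2-nullcline in h requires gNa > 0")
    V2 = np.arange(v2_range[0], v2_range[1] + dv / 2, dv)
    V2 = V2[np.abs(V2 - params.ENa) > 1e-6]
    h = _h_on_nullcline(params, V1_fixed, V2)
    ok = np.isfinite(h) & (h >= h_clip[0]) & (h <= h_clip[1])
    V2, h = V2[ok], h[ok]
    return NullclineCurve(V2=V2, h=h, V1_fixed=V1_fixed, branch=_label_branches(V2, h))


def left_knee(curve: NullclineCurve) -> tuple[float, float] | None:
    """Local maximum of h along the nullcline with 0 < h < 1, or None.

    The knee is located on the sampled curve and refined by a quadratic
    fit through the three samples around the discrete maximum.
    """
    V2, h = curve.V2, curve.h
    if len(h) < 3:
        return None
    interior = np.nonzero((h[1:-1] > h[:-2]) & (h[1:-1] >= h[2:]))[0] + 1
    interior = [i for i in interior if 0.0 < h[i] < 1.0]
    if not interior:
        return None
    i = min(interior, key=lambda j: V2[j])  # leftmost local maximum
    if i == 0 or i == len(h) - 1:
        return float(V2[i]), float(h[i])
    # quadratic refinement through (i-1, i, i+1)
    x = V2[i - 1 : i + 2]
    y = h[i - 1 : i + 2]
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
    b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
    if a == 0:
        return float(x[1]), float(y[1])
    xv = -b / (2 * a)
    c = y[1] - a * x[1] ** 2 - b * x[1]
    return float(xv), float(a * xv**2 + b * xv + c)


def h_nullcline(V2: np.ndarray | float) -> np.ndarray | float:
    """The h-nullcline h = h_inf(V2), identical for all coupling configurations."""
    return ch.h_inf(V2)


def fixed_points(
    params: TwoCompartmentParams,
    V1_fixed: float,
    v2_range: tuple[float, float] = (-80.0, 60.0),
    dv: float = 0.05,
) -> list[tuple[float, float, str]]:
    """Intersections of the V2-nullcline with h = h_inf(V2).

    Roots are bracketed by sign changes on a fine grid and polished with
    Brent's method. Returns (V2, h, branch) triples; branch labels follow
    the nullcline's knee structure at this V1.
    """
    curve = v2_nullcline(params, V1_fixed, v2_range, dv, h_clip=(-np.inf, np.inf))

    def f(v):
        return float(_h_on_nullcline(params, V1_fixed, np.asarray([v]))[0] - ch.h_inf(v))

    vals = curve.h - np.asarray(ch.h_inf(curve.V2))
    roots: list[float] = []
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    for i in sign_change:
        a, b = curve.V2[i], curve.V2[i + 1]
        if b - a > 2 * dv:  # gap across an excluded (singular/clipped) region
            continue
        roots.append(float(optimize.brentq(f, a, b, xtol=1e-12)))
    for i in np.nonzero(vals == 0)[0]:
        roots.append(float(curve.V2[i]))

    plotted = v2_nullcline(params, V1_fixed, v2_range, dv)
    out = []
    for v in sorted(set(np.round(roots, 9))):
        hv = float(ch.h_inf(v))
        j = int(np.argmin(np.abs(plotted.V2 - v))) if len(plotted) else 0
        label = str(plotted.branch[j]) if len(plotted) else "left"
        out.append((v, hv, label))
    return out
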