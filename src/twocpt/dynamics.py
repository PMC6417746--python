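"""Integration of the full two-compartment system and spike detection.

The membrane equations are

    c1 V1' = -g1 (V1 - Elk) - gc (V1 - V2) - I_KLT1 - I_syn + I_app
    c2 V2' = -g2 (V2 - Elk) - gc (V2 - V1) - I_KLT2 - I_Na

with I_syn = g_syn(t) (V1 - E_syn) (depolarizing for V1 < E_syn) and
positive injected current I_app depolarizing. Gating variables follow
first-order relaxation kinetics (see :mod:`twocpt.channels`).

Two integration paths are provided. The default is a compiled fixed-step
exponential-Euler scheme (:mod:`twocpt._engine`), fast enough for the
stochastic firing-rate protocols. A variable-step stiff solver
(``method="lsoda"``, via :func:`scipy.integrate.solve_ivp`) serves as an
independent cross-check of the compiled path.

Spikes are detected post hoc as upward crossings of a voltage threshold on
V2 (-20 mV by default: spike peaks range from ~0 mV in strongly
forward-coupled models to ~+40 mV in weakly coupled ones, while
subthreshold activity stays well below), separated by a dead time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import channels as ch
from ._engine import integrate as _integrate_exp_euler
from .params import TwoCompartmentParams
from .stimuli import Stimulus

__all__ = [
    "CellState",
    "SimResult",
    "SPIKE_THRESHOLD",
    "SPIKE_DEAD_TIME",
    "DEFAULT_DT",
    "resting_state",
    "derivatives",
    "simulate",
    "detect_spikes",
]

SPIKE_THRESHOLD = -20.0  # mV, on V2
SPIKE_DEAD_TIME = 0.5  # ms
DEFAULT_DT = 1e-4  # ms (0.1 us) fixed step of the exponential-Euler engine
DEFAULT_RECORD_DT = 0.01  # ms (10 us) output sampling


class CellState(NamedTuple):
    """Full model state (V1, V2 in mV; gates dimensionless in [0, 1])."""

    V1: float
    V2: float
    h: float
    w1: float
    w2: float


@dataclass(frozen=True)
class SimResult:
    """Time-sampled trajectory plus detected spike times."""

    t: np.ndarray  # ms
    V1: np.ndarray
    V2: np.ndarray
    h: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    spike_times: np.ndarray  # ms
    metadata: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return int(len(self.spike_times))

    def state_at(self, t: float) -> CellState:
        """Linearly interpolated state at time ``t``."""
        return CellState(
            *(float(np.interp(t, self.t, x)) for x in (self.V1, self.V2, self.h, self.w1, self.w2))
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_ms": self.t, "V1_mV": self.V1, "V2_mV": self.V2, "h": self.h, "w1": self.w1, "w2": self.w2}
        )


def resting_state(params: TwoCompartmentParams) -> CellState:
    """Exact equilibrium under zero input (by the rest-correction terms)."""
    Vr = params.Vrest
    return CellState(Vr, Vr, float(ch.h_inf(Vr)), float(ch.w_inf(Vr)), float(ch.w_inf(Vr)))


def derivatives(
    state: CellState | tuple,
    t: float,
    params: TwoCompartmentParams,
    stimulus: Stimulus,
) -> np.ndarray:
    """Right-hand side of the full system at one instant (reference path).

    This plain-Python implementation defines the model; the compiled engine
    must agree with it and tests hold it to that.
    """
    V1, V2, h, w1, w2 = state
    p = params
    Vr = p.Vrest
    na = ch.NaChannel(p.gNa, p.ENa)
    k1 = ch.KltChannel(p.gKLT1, p.EK, p.klt_mode)
    k2 = ch.KltChannel(p.gKLT2, p.EK, p.klt_mode)
    w_r = float(ch.w_inf(Vr))
    w1_eff = w1 if p.klt_mode == "dynamic" else w_r
    w2_eff = w2 if p.klt_mode == "dynamic" else w_r

    gsyn = float(stimulus.g_syn(t))
    iapp = float(stimulus.i_app(t))
    i_syn = gsyn * (V1 - stimulus.E_syn)

    dV1 = (
        -p.g1 * (V1 - p.Elk)
        - p.gc * (V1 - V2)
        - ch.klt_current(V1, w1_eff, k1, Vr)
        - i_syn
        + iapp
    ) / p.c1
    dV2 = (
        -p.g2 * (V2 - p.Elk)
        - p.gc * (V2 - V1)
        - ch.klt_current(V2, w2_eff, k2, Vr)
        - ch.na_current(V2, h, na, Vr)
    ) / p.c2
    dh = (float(ch.h_inf(V2)) - h) / float(ch.tau_h(V2))
    if p.klt_mode == "dynamic":
        dw1 = (float(ch.w_inf(V1)) - w1) / float(ch.tau_w(V1))
        dw2 = (float(ch.w_inf(V2)) - w2) / float(ch.tau_w(V2))
    else:
        dw1 = 0.0
        dw2 = 0.0
    return np.array([dV1, dV2, dh, dw1, dw2])


def detect_spikes(
    t: np.ndarray,
    V2: np.ndarray,
    threshold: float = SPIKE_THRESHOLD,
    dead_time: float = SPIKE_DEAD_TIME,
) -> np.ndarray:
    """Times of upward threshold crossings of V2, separated by >= dead_time.

    Crossing times are linearly interpolated between samples. Returns an
    empty array when the trace never crosses.
    """
    t = np.asarray(t, dtype=float)
    V2 = np.asarray(V2, dtype=float)
    below = V2[:-1] < threshold
    above = V2[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.zeros(0)
    frac = (threshold - V2[idx]) / (V2[idx + 1] - V2[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    out = [times[0]]
    for tt in times[1:]:
        if tt - out[-1] >= dead_time:
            out.append(tt)
    return np.asarray(out)


def simulate(
    params: TwoCompartmentParams,
    stimulus: Stimulus,
    duration: float,
    *,
    dt: float = DEFAULT_DT,
    record_dt: float = DEFAULT_RECORD_DT,
    method: str = "exp_euler",
    initial: CellState | None = None,
    clamp_v1: bool = False,
    threshold: float = SPIKE_THRESHOLD,
    dead_time: float = SPIKE_DEAD_TIME,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> SimResult:
    """Integrate the model for ``duration`` ms and detect spikes.

    Deterministic: identical arguments always produce identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if initial is None:
        initial = resting_state(params)

    if method == "exp_euler":
        t, V1, V2, h, w1, w2 = _integrate_exp_euler(
            params, stimulus, duration, dt, record_dt, tuple(initial), clamp_v1
        )
    elif method == "lsoda":
        from scipy.integrate import solve_ivp

        def rhs(tt, y):
            d = derivatives(tuple(y), tt, params, stimulus)
            if clamp_v1:
                d[0] = 0.0
            return d

        t_eval = np.arange(0.0, duration + record_dt / 2, record_dt)
        sol = solve_ivp(
            rhs,
            (0.0, duration),
            np.array(initial, dtype=float),
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            max_step=0.05,
        )
        if not sol.success:
            raise RuntimeError(
                f"stiff solver failed: {sol.message} (rtol={rtol}, atol={atol}, "
                f"last state={sol.y[:, -1] if sol.y.size else None})"
            )
        t, (V1, V2, h, w1, w2) = sol.t, sol.y
    else:
        raise ValueError(f"unknown method {method!r}")

    spikes = detect_spikes(t, V2, threshold, dead_time)
    return SimResult(
        t=t,
        V1=V1,
        V2=V2,
        h=h,
        w1=w1,
        w2=w2,
        spike_times=spikes,
        metadata={
            "method": method,
            "dt": dt,
            "record_dt": record_dt,
            "threshold": threshold,
            "dead_time": dead_time,
            "stimulus": stimulus.description,
            "clamp_v1": clamp_v1,
        },
    )
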