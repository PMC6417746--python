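"""Voltage-gated currents: reduced sodium and low-threshold potassium (KLT).

Kinetics follow the Rothman–Manis lineage of auditory brainstem models,
temperature-adjusted to 35 C. Sodium activation is instantaneous
(m = m_inf(V2)); inactivation h is the single dynamic sodium gate. The KLT
inactivation gate z is slow and is always held frozen at its resting value
z_inf(Vrest); the activation gate w is dynamic only in "dynamic" KLT mode.

Both currents carry a constant rest-correction term so that they vanish
exactly at the resting potential, which keeps Vrest an equilibrium of the
full system without retuning the leak reversal.

Note on w_inf: the activation curve is taken as the rising Boltzmann
w_inf(V) = 1/(1 + exp(-(V+65)/6)). An activation gate must open with
depolarization for KLT to act as a negative feedback; the falling form
would describe inactivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "m_inf",
    "h_inf",
    "tau_h",
    "h_gate",
    "w_inf",
    "tau_w",
    "w_gate",
    "z_inf",
    "NaChannel",
    "KltChannel",
    "na_current",
    "klt_current",
    "allocate_klt",
]

ENA_DEFAULT = 55.0  # mV
EK_DEFAULT = -106.0  # mV

# Sodium activation midpoint/slope (Rothman-Manis lineage). Exposed at module
# level so alternative calibrations can be swapped in one place.
M_HALF = -38.0
M_SLOPE = 7.0


def m_inf(V: np.ndarray | float) -> np.ndarray | float:
    """Instantaneous sodium activation."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, dtype=float) - M_HALF) / M_SLOPE))


def h_inf(V: np.ndarray | float) -> np.ndarray | float:
    """Steady-state sodium inactivation; strictly decreasing, midpoint -65 mV."""
    return 1.0 / (1.0 + np.exp((np.asarray(V, dtype=float) + 65.0) / 6.0))


def tau_h(V: np.ndarray | float) -> np.ndarray | float:
    """Sodium inactivation time constant, ms (35 C)."""
    V = np.asarray(V, dtype=float)
    return 0.24 * (100.0 / (7.0 * np.exp((V + 60.0) / 11.0) + 10.0 * np.exp(-(V + 60.0) / 25.0)) + 0.6)


def h_gate(V: float) -> tuple[float, float]:
    """(h_inf, tau_h) at a voltage."""
    return float(h_inf(V)), float(tau_h(V))


def w_inf(V: np.ndarray | float) -> np.ndarray | float:
    """Steady-state KLT activation; strictly increasing, midpoint -65 mV."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, dtype=float) + 65.0) / 6.0))


def tau_w(V: np.ndarray | float) -> np.ndarray | float:
    """KLT activation time constant, ms (35 C)."""
    V = np.asarray(V, dtype=float)
    return 0.46 * (100.0 / (6.0 * np.exp((V + 75.0) / 12.15) + 24.0 * np.exp(-(V + 75.0) / 25.0)) + 0.55)


def w_gate(V: float) -> tuple[float, float]:
    """(w_inf, tau_w) at a voltage."""
    return float(w_inf(V)), float(tau_w(V))


def z_inf(V: np.ndarray | float) -> np.ndarray | float:
    """Steady-state KLT inactivation (always evaluated frozen, at Vrest)."""
    V = np.asarray(V, dtype=float)
    return 0.78 / (1.0 + np.exp((V + 57.0) / 5.44)) + 0.22


@dataclass(frozen=True)
class NaChannel:
    """Reduced spike-generating sodium current in Cpt2."""

    gNa: float  # nS
    ENa: float = ENA_DEFAULT


@dataclass(frozen=True)
class KltChannel:
    """Low-threshold potassium current in one compartment."""

    gKLT: float  # nS
    EK: float = EK_DEFAULT
    mode: str = "frozen"  # "frozen" | "dynamic"


def na_current(V2: float, h: float, channel: NaChannel, Vrest: float) -> float:
    """I_Na = gNa * m_inf^3(V2) * h * (V2 - ENa), corrected to zero at rest. pA."""
    g, ENa = channel.gNa, channel.ENa
    rest = g * float(m_inf(Vrest)) ** 3 * float(h_inf(Vrest)) * (Vrest - ENa)
    return g * float(m_inf(V2)) ** 3 * h * (V2 - ENa) - rest


def klt_current(Vi: float, w: float, channel: KltChannel, Vrest: float) -> float:
    """I_KLT = gKLT * w^4 * z_inf(Vrest) * (Vi - EK), corrected to zero at rest. pA.

    The slow inactivation gate z is frozen at its resting steady state.
    """
    g, EK = channel.gKLT, channel.EK
    z_r = float(z_inf(Vrest))
    rest = g * float(w_inf(Vrest)) ** 4 * z_r * (Vrest - EK)
    return g * w**4 * z_r * (Vi - EK) - rest


def allocate_klt(g_lk: float, fraction: float, Vrest: float) -> tuple[float, float]:
    """Split a compartment's leak into (reduced leak, KLT conductance).

    A ``fraction`` of the resting conductance is carried by KLT instead of
    leak, preserving the total conductance at rest exactly:

        g_leak_new + gKLT * w_inf^4(Vrest) * z_inf(Vrest) = g_lk

    Returns (g_leak_new, gKLT) in nS.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    g_leak_new = (1.0 - fraction) * g_lk
    if fraction == 0.0:
        return g_leak_new, 0.0
    gklt = fraction * g_lk / (float(w_inf(Vrest)) ** 4 * float(z_inf(Vrest)))
    return g_leak_new, gklt
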