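"""Passive parameterization of the two-compartment model by coupling strength.

The model separates a neuron into an input compartment (Cpt1: soma and
dendrites) and a spike-generating compartment (Cpt2: axon initial segment).
Rather than specifying the five passive parameters (g1, g2, gc, c1, c2)
directly, the family of models is indexed by two voltage-attenuation
factors:

* ``kappa_fwd`` (soma-to-axon): the steady-state ratio U2/U1 for constant
  current injected into Cpt1,
* ``kappa_back`` (axon-to-soma): the steady-state ratio U1/U2 for constant
  current injected into Cpt2,

where U_i = V_i - E_lk. Given measured somatic properties (input
resistance, membrane decay time constant, resting potential) and the area
ratio alpha = A2/A1, every coupling pair maps to a unique conductance set
that leaves the passive dynamics of Cpt1 (nearly) invariant:

    gc = kappa_back / (Rin * (1 - kappa_fwd * kappa_back))
    g1 = gc * (1/kappa_back - 1)
    g2 = gc * (1/kappa_fwd - 1)
    c1 = tau_exp * (1 - kappa_fwd * kappa_back) * (g1 + gc)
    c2 = alpha * c1

Units are mV, ms, nS, pA, pF throughout (self-consistent: nS*mV = pA and
pF*mV/ms = pA). Input resistance is accepted in MOhm and converted once
here (1/MOhm = 1000 nS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

__all__ = [
    "PassiveCellSpec",
    "CouplingConfig",
    "TwoCompartmentParams",
    "MSO_SPEC",
    "WEAKLY_COUPLED",
    "FORWARD_COUPLED",
    "STRONGLY_COUPLED",
    "build_two_compartment_params",
    "coupling_from_conductances",
    "timescale_ratio",
    "coupling_grid",
]

#: Maximum allowed ratio kappa_fwd / kappa_back. Together with a small area
#: ratio alpha this keeps tau2/tau1 = alpha * kappa_fwd / kappa_back small,
#: i.e. preserves the slow(soma)/fast(axon) timescale separation on which
#: the Cpt1-invariance of the parameterization rests.
MAX_KAPPA_RATIO = 10.0


class CouplingError(ValueError):
    """Invalid coupling configuration (degenerate or outside the allowed wedge)."""


@dataclass(frozen=True)
class PassiveCellSpec:
    """Measured passive constraints plus geometric assumptions.

    Attributes
    ----------
    Rin : float
        Steady-state input resistance at the soma, MOhm.
    tau_exp : float
        Exponential decay time constant of somatic voltage, ms.
    Vrest : float
        Resting potential, mV. Equals the leak reversal in the passive model.
    alpha : float
        Area ratio A2/A1 (axon/soma), dimensionless; must be small.
    Cm : float
        Specific membrane capacitance, uF/cm^2 (used only for area
        bookkeeping; the dynamics use c1, c2 directly).
    """

    Rin: float = 8.5
    tau_exp: float = 0.34
    Vrest: float = -58.0
    alpha: float = 0.01
    Cm: float = 0.9

    def __post_init__(self) -> None:
        if self.Rin <= 0:
            raise ValueError("Rin must be positive")
        if self.tau_exp <= 0:
            raise ValueError("tau_exp must be positive")
        if not 0 < self.alpha <= 0.1:
            raise ValueError("alpha must lie in (0, 0.1]")
        if self.Cm <= 0:
            raise ValueError("Cm must be positive")

    @property
    def g_total_rest(self) -> float:
        """Total resting conductance seen from Cpt1, nS (= 1000/Rin/(1-kf*kb) ... see build)."""
        return 1000.0 / self.Rin

    @property
    def c1(self) -> float:
        """Cpt1 capacitance, pF (= tau_exp / Rin, independent of coupling)."""
        return 1000.0 * self.tau_exp / self.Rin

    @property
    def area1_um2(self) -> float:
        """Implied Cpt1 membrane area in um^2 at the given Cm."""
        # c1 [pF] / Cm [uF/cm^2] ; 1 uF/cm^2 = 0.01 pF/um^2
        return self.c1 / (self.Cm * 0.01)


@dataclass(frozen=True, order=True)
class CouplingConfig:
    """One point in the two-dimensional space of coupling strengths."""

    kappa_fwd: float
    kappa_back: float

    def __post_init__(self) -> None:
        kf, kb = self.kappa_fwd, self.kappa_back
        if not (0.0 < kf < 1.0) or not (0.0 < kb < 1.0):
            raise CouplingError(f"coupling parameters must lie in (0, 1), got ({kf}, {kb})")
        if kf * kb >= 1.0:
            raise CouplingError("degenerate coupling: kappa_fwd * kappa_back must be < 1")
        if kf < kb:
            raise CouplingError(
                f"forward coupling must be at least backward coupling (kf={kf} < kb={kb})"
            )
        if kf / kb > MAX_KAPPA_RATIO:
            raise CouplingError(
                f"kappa_fwd/kappa_back = {kf / kb:.3g} exceeds {MAX_KAPPA_RATIO}; "
                "timescale separation no longer holds"
            )


# The three named configurations examined throughout.
WEAKLY_COUPLED = CouplingConfig(0.3, 0.2)
FORWARD_COUPLED = CouplingConfig(0.8, 0.2)
STRONGLY_COUPLED = CouplingConfig(0.8, 0.7)

#: Default passive spec for gerbil MSO principal cells.
MSO_SPEC = PassiveCellSpec()


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Concrete parameter set for one model instance.

    Conductances in nS, capacitances in pF, voltages in mV. Channel fields
    describe the active currents layered on the passive skeleton; with
    ``gNa = 0`` and frozen KLT the model is purely passive.
    """

    g1: float
    g2: float
    gc: float
    c1: float
    c2: float
    Elk: float
    # --- channel block ---
    gNa: float = 0.0
    ENa: float = 55.0
    EK: float = -106.0
    gKLT1: float = 0.0
    gKLT2: float = 0.0
    klt_mode: str = "frozen"  # "frozen" | "dynamic"
    # provenance (not used by the dynamics)
    coupling: CouplingConfig | None = None
    spec: PassiveCellSpec = field(default=MSO_SPEC)

    def __post_init__(self) -> None:
        for name in ("g1", "g2", "gc", "gNa", "gKLT1", "gKLT2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("capacitances must be positive")
        if self.klt_mode not in ("frozen", "dynamic"):
            raise ValueError("klt_mode must be 'frozen' or 'dynamic'")

    @property
    def Vrest(self) -> float:
        return self.Elk

    @property
    def tau1(self) -> float:
        """Cpt1 time constant c1/(g1+gc), ms."""
        return self.c1 / (self.g1 + self.gc)

    @property
    def tau2(self) -> float:
        """Cpt2 time constant c2/(g2+gc), ms."""
        return self.c2 / (self.g2 + self.gc)

    @property
    def epsilon(self) -> float:
        """Timescale-separation parameter tau2/tau1."""
        return self.tau2 / self.tau1

    def with_gna(self, gNa: float) -> "TwoCompartmentParams":
        return replace(self, gNa=gNa)

    def with_klt(self, gKLT1: float = 0.0, gKLT2: float = 0.0, mode: str = "dynamic") -> "TwoCompartmentParams":
        return replace(self, gKLT1=gKLT1, gKLT2=gKLT2, klt_mode=mode)


def build_two_compartment_params(
    spec: PassiveCellSpec, coupling: CouplingConfig
) -> TwoCompartmentParams:
    """Construct the unique passive parameter set for a coupling pair.

    Guarantees (up to O(epsilon) terms) that the passive response of Cpt1
    is the same for every valid coupling pair: the steady-state input
    resistance at Cpt1 is exactly ``spec.Rin`` and c1 = tau_exp/Rin.
    """
    kf, kb = coupling.kappa_fwd, coupling.kappa_back
    one_minus = 1.0 - kf * kb
    if one_minus <= 0.0:  # unreachable through CouplingConfig, kept for direct calls
        raise CouplingError("degenerate coupling: kappa_fwd * kappa_back must be < 1")
    g_in = 1000.0 / spec.Rin  # 1/MOhm -> nS (this is (g1+gc)*(1-kf*kb))
    gc = kb * g_in / one_minus
    g1 = gc * (1.0 / kb - 1.0)
    g2 = gc * (1.0 / kf - 1.0)
    c1 = spec.tau_exp * one_minus * (g1 + gc)
    c2 = spec.alpha * c1
    return TwoCompartmentParams(
        g1=g1, g2=g2, gc=gc, c1=c1, c2=c2, Elk=spec.Vrest, coupling=coupling, spec=spec
    )


def coupling_from_conductances(g1: float, g2: float, gc: float) -> tuple[float, float]:
    """Recover (kappa_fwd, kappa_back) = (gc/(g2+gc), gc/(g1+gc)) from conductances."""
    if min(g1, g2, gc) < 0:
        raise ValueError("conductances must be nonnegative")
    if g2 + gc == 0 or g1 + gc == 0:
        raise ZeroDivisionError("cannot define coupling with zero total conductance")
    return gc / (g2 + gc), gc / (g1 + gc)


def timescale_ratio(spec: PassiveCellSpec, coupling: CouplingConfig) -> float:
    """tau2/tau1 = alpha * kappa_fwd / kappa_back for the constructed model."""
    if coupling.kappa_back == 0:
        raise ZeroDivisionError("kappa_back must be nonzero")
    return spec.alpha * coupling.kappa_fwd / coupling.kappa_back


def coupling_grid(
    step: float = 0.05,
    bounds: tuple[float, float] = (0.1, 0.9),
    max_ratio: float = MAX_KAPPA_RATIO,
) -> list[CouplingConfig]:
    """Triangular grid of valid coupling pairs.

    Enumerates kappa values ``bounds[0], bounds[0]+step, ...`` up to
    ``bounds[1]`` on both axes and keeps pairs satisfying the model's
    restrictions (kf >= kb, kf/kb <= max_ratio, kf*kb < 1). Ordering is
    row-major: by kappa_back, then kappa_fwd.
    """
    if not 0.0 < step < 1.0:
        raise ValueError("step must lie in (0, 1)")
    lo, hi = bounds
    n = int(round((hi - lo) / step))
    values = [lo + i * step for i in range(n + 1)]
    values = [v for v in values if v <= hi + 1e-12]
    grid: list[CouplingConfig] = []
    for kb in values:
        for kf in values:
            if kf < kb or kf * kb >= 1.0 or kf / kb > max_ratio * (1 + 1e-12):
                continue
            if not (0.0 < kf < 1.0 and 0.0 < kb < 1.0):
                continue
            grid.append(CouplingConfig(round(kf, 12), round(kb, 12)))
    if not grid:
        raise ValueError("bounds and step exclude all valid coupling pairs")
    return grid
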