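"""Stimulus construction: current steps/ramps, EPSG events, afferent trains.

Synaptic drive is built from a unitary excitatory post-synaptic conductance
(EPSG) kernel, a double exponential

    g_syn(t) = 125.25 * (exp(-t/0.18) - exp(-t/0.10))   [nS, t in ms]

whose amplitude is scaled so that a single unitary event depolarizes the
soma compartment by roughly 6 mV. Conductance is converted to current at
the membrane via I_syn = g_syn(t) * (V1 - E_syn) with E_syn = 0 mV.

Phase-locked afferent spike trains stand in for an auditory-periphery
model: each of five fibers per ear is an inhomogeneous point process with a
von Mises rate profile locked to the tone frequency, thinned by an absolute
refractory period. The concentration is chosen per frequency so that
phase locking (vector strength) degrades with frequency as in the auditory
nerve. This stand-in reproduces the statistical structure the coincidence
analysis relies on (independent fibers, frequency-dependent phase locking),
not the detailed cochlear transduction chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "EPSG_AMPLITUDE",
    "EPSG_TAU_DECAY",
    "EPSG_TAU_RISE",
    "E_SYN",
    "epsg_kernel",
    "epsg_peak",
    "conductance_train",
    "step_current",
    "ramp_current",
    "Stimulus",
    "AfferentTrainSet",
    "phase_locked_trains",
    "vector_strength",
    "vs_target_for_freq",
]

EPSG_AMPLITUDE = 125.25  # nS
EPSG_TAU_DECAY = 0.18  # ms
EPSG_TAU_RISE = 0.10  # ms
E_SYN = 0.0  # mV

#: Default vector-strength targets for the synthetic afferent generator,
#: interpolated linearly between the listed frequencies (Hz).
VS_TARGETS = {200: 0.80, 300: 0.75, 400: 0.70, 500: 0.65, 600: 0.60, 700: 0.55}
DEFAULT_FIBER_RATE = 200.0  # spikes/s per fiber
DEFAULT_REFRACTORY = 0.75  # ms, absolute refractory gap per fiber


def epsg_kernel(t: np.ndarray | float) -> np.ndarray | float:
    """Unitary EPSG waveform, nS. Zero for t <= 0 (causal)."""
    t = np.asarray(t, dtype=float)
    out = np.where(
        t > 0.0,
        EPSG_AMPLITUDE * (np.exp(-t / EPSG_TAU_DECAY) - np.exp(-t / EPSG_TAU_RISE)),
        0.0,
    )
    return out if out.ndim else float(out)


def epsg_peak() -> tuple[float, float]:
    """Closed-form (time, value) of the unitary EPSG maximum."""
    a, b = 1.0 / EPSG_TAU_RISE, 1.0 / EPSG_TAU_DECAY
    t_peak = math.log(a / b) / (a - b)
    return t_peak, float(epsg_kernel(t_peak))


def conductance_train(events):
    """Linear superposition of scaled, shifted EPSG kernels.

    Parameters
    ----------
    events : sequence of (time_ms, scale)
        Scale is in units of the unitary event (2.0 = two simultaneous
        unitary inputs).

    Returns
    -------
    callable mapping t (scalar or array, ms) to conductance (nS).
    """
    ev = np.asarray(list(events), dtype=float).reshape(-1, 2)

    def g(t):
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t)
        for te, sc in ev:
            total = total + sc * epsg_kernel(t - te)
        return total if total.ndim else float(total)

    return g


def step_current(amplitude: float, onset: float, duration: float):
    """Piecewise-constant injected current, pA; zero outside [onset, onset+duration)."""

    def i(t):
        t = np.asarray(t, dtype=float)
        out = np.where((t >= onset) & (t < onset + duration), amplitude, 0.0)
        return out if out.ndim else float(out)

    return i


def ramp_current(slope: float, peak: float, onset: float):
    """Linear current ramp (pA) rising at ``slope`` pA/ms to ``peak``, then sustained."""
    if slope <= 0:
        raise ValueError("ramp slope must be positive")
    t_rise = peak / slope

    def i(t):
        t = np.asarray(t, dtype=float)
        out = np.clip((t - onset) * slope, 0.0, peak)
        return out if out.ndim else float(out)

    i.t_rise = t_rise  # type: ignore[attr-defined]
    return i


@dataclass(frozen=True)
class Stimulus:
    """Stimulus description consumed by the simulator.

    ``syn_events`` are (time ms, scale) rows driving the EPSG kernel into
    Cpt1; ``iapp_breaks`` are (time ms, pA) breakpoints of a piecewise-linear
    injected current (held at the last value afterwards).
    """

    syn_events: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    iapp_breaks: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    E_syn: float = E_SYN
    description: str = "zero"

    @staticmethod
    def zero() -> "Stimulus":
        return Stimulus()

    @staticmethod
    def epsg(events) -> "Stimulus":
        ev = np.asarray(list(events), dtype=float).reshape(-1, 2)
        ev = ev[np.argsort(ev[:, 0], kind="stable")]
        if ev.size and ev[0, 0] < 0:
            raise ValueError("EPSG event times must be nonnegative")
        return Stimulus(syn_events=ev, description=f"epsg_train(n={len(ev)})")

    @staticmethod
    def epsg_pair(t0: float, delay: float, scale: float = 1.0) -> "Stimulus":
        """Two EPSG events of equal scale separated by ``delay`` ms."""
        return Stimulus(
            syn_events=np.array([[t0, scale], [t0 + delay, scale]]),
            description=f"epsg_pair(delay={delay}, scale={scale})",
        )

    @staticmethod
    def step(amplitude: float, onset: float = 5.0, duration: float = 200.0) -> "Stimulus":
        br = np.array(
            [
                [0.0, 0.0],
                [onset, 0.0],
                [onset, amplitude],
                [onset + duration, amplitude],
                [onset + duration, 0.0],
            ]
        )
        return Stimulus(iapp_breaks=br, description=f"step({amplitude} pA)")

    @staticmethod
    def ramp(slope: float, peak: float = 2500.0, onset: float = 5.0) -> "Stimulus":
        if slope <= 0:
            raise ValueError("ramp slope must be positive")
        br = np.array([[0.0, 0.0], [onset, 0.0], [onset + peak / slope, peak]])
        return Stimulus(iapp_breaks=br, description=f"ramp({slope} pA/ms, peak {peak} pA)")

    def g_syn(self, t):
        """Total synaptic conductance waveform (nS) at times ``t``."""
        return conductance_train(self.syn_events)(t)

    def i_app(self, t):
        """Injected current (pA) at times ``t`` (piecewise-linear interpolation)."""
        t = np.asarray(t, dtype=float)
        if self.iapp_breaks.size == 0:
            out = np.zeros_like(t)
            return out if out.ndim else float(out)
        out = np.interp(t, self.iapp_breaks[:, 0], self.iapp_breaks[:, 1])
        return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Synthetic phase-locked afferent trains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AfferentTrainSet:
    """Spike times of the afferent fibers driving the model (5 per ear)."""

    side_a: tuple[np.ndarray, ...]
    side_b: tuple[np.ndarray, ...]
    freq: float  # Hz
    mean_rate: float  # spikes/s target per fiber
    vs_target: float
    side_delay: float  # ms applied to side B
    refractory: float  # ms
    seed: int

    @property
    def fibers(self) -> list[np.ndarray]:
        return list(self.side_a) + list(self.side_b)

    def to_events(self, scale: float = 1.0) -> np.ndarray:
        """Merge all fibers into sorted (time, scale) EPSG events."""
        if any(len(f) for f in self.fibers):
            times = np.sort(np.concatenate([f for f in self.fibers]))
        else:
            times = np.zeros(0)
        return np.column_stack([times, np.full_like(times, scale)])

    def to_stimulus(self, scale: float = 1.0) -> Stimulus:
        ev = self.to_events(scale)
        return Stimulus(
            syn_events=ev,
            description=f"afferents({self.freq} Hz, delay {self.side_delay} ms)",
        )


def vs_target_for_freq(freq: float) -> float:
    """Vector-strength target at a tone frequency, linear between anchors."""
    fs = np.array(sorted(VS_TARGETS))
    vs = np.array([VS_TARGETS[f] for f in fs])
    return float(np.interp(freq, fs, vs))


def _von_mises_kappa(vs: float) -> float:
    """Concentration kappa with I1(kappa)/I0(kappa) = vs."""
    if not 0.0 < vs < 1.0:
        raise ValueError("vector strength target must lie in (0, 1)")
    return float(
        optimize.brentq(lambda k: special.i1(k) / special.i0(k) - vs, 1e-6, 700.0)
    )


def _one_fiber(
    rng: np.random.Generator,
    freq: float,
    duration: float,
    base_rate: float,
    kappa: float,
    phase: float,
    refractory: float,
) -> np.ndarray:
    """Lewis thinning of a von Mises-rate Poisson process + dead-time pruning."""
    i0 = special.i0(kappa)
    lam_max = base_rate * math.exp(kappa) / i0  # spikes/s
    # homogeneous candidates on [0, duration] ms
    n_exp = lam_max * duration / 1000.0
    n = rng.poisson(n_exp)
    cand = np.sort(rng.uniform(0.0, duration, size=n))
    lam = base_rate * np.exp(kappa * np.cos(2.0 * math.pi * freq * cand / 1000.0 - phase)) / i0
    keep = rng.uniform(0.0, 1.0, size=n) < lam / lam_max
    cand = cand[keep]
    # absolute refractory: sequential pruning
    out = []
    last = -math.inf
    for t in cand:
        if t - last >= refractory:
            out.append(t)
            last = t
    return np.asarray(out)


def phase_locked_trains(
    freq: float,
    duration: float,
    n_fibers: int = 5,
    side_delay: float = 0.0,
    mean_rate: float = DEFAULT_FIBER_RATE,
    vs_target: float | None = None,
    refractory: float = DEFAULT_REFRACTORY,
    seed: int = 0,
) -> AfferentTrainSet:
    """Generate one trial of phase-locked afferent spike trains.

    Each fiber is an independent inhomogeneous point process with rate
    r(t) proportional to exp(kappa * cos(2*pi*f*t - phi)), normalized so the
    post-refractory mean rate approximates ``mean_rate``, then thinned by an
    absolute refractory gap. Side B is delayed by ``side_delay`` ms
    (0 = coincident; half a period = anti-phase; 0.5 ms = fixed delay).

    The same seed always yields the same trains; fibers use independent
    substreams spawned from the master seed, so any fiber is reproducible
    in isolation.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if mean_rate <= 0:
        raise ValueError("mean_rate must be positive")
    if vs_target is None:
        vs_target = vs_target_for_freq(freq)
    kappa = _von_mises_kappa(vs_target)
    # inflate the driving rate to offset dead-time losses
    base = mean_rate / max(1e-9, 1.0 - mean_rate * refractory / 1000.0)
    streams = np.random.SeedSequence(seed).spawn(2 * n_fibers)
    phase_b = 2.0 * math.pi * freq * side_delay / 1000.0
    side_a = tuple(
        _one_fiber(np.random.default_rng(streams[i]), freq, duration, base, kappa, 0.0, refractory)
        for i in range(n_fibers)
    )
    side_b = tuple(
        _one_fiber(
            np.random.default_rng(streams[n_fibers + i]),
            freq,
            duration,
            base,
            kappa,
            phase_b,
            refractory,
        )
        for i in range(n_fibers)
    )
    return AfferentTrainSet(
        side_a=side_a,
        side_b=side_b,
        freq=freq,
        mean_rate=mean_rate,
        vs_target=vs_target,
        side_delay=side_delay,
        refractory=refractory,
        seed=seed,
    )


def vector_strength(times: np.ndarray, freq: float) -> float:
    """|sum exp(i*theta)| / N for spike phases theta = 2*pi*f*t."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return float("nan")
    th = 2.0 * math.pi * freq * times / 1000.0
    return float(abs(np.exp(1j * th).mean()))
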