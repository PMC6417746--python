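"""Measurement protocols characterizing coincidence detection.

Implemented procedures:

* :func:`find_gna_ref` — reference sodium conductance: the smallest gNa at
  which a pair of simultaneous unitary EPSGs evokes a spike. Anchors all
  gNa sweeps so models with wildly different absolute excitability can be
  compared on a common footing.
* :func:`coincidence_sensitivity` — ROC-style sweep: firing rate to
  coincident vs non-coincident afferent ensembles across a gNa range;
  sensitivity is the maximum firing-rate difference over the sweep.
* :func:`classify_firing_pattern` / :func:`find_gna_tonic` — response to
  sustained current steps (quiescent / phasic / tonic) and the repetitive-
  firing boundary gNa_tonic, found by simulation-based classification with
  bisection over gNa (in place of numerical continuation).
* :func:`ramp_threshold_gna` / :func:`delta_gna` — slope sensitivity via
  threshold gNa for current ramps of different slopes.
* :func:`refractory_period` / :func:`delay_threshold_curve` — the minimum
  delay at which a pair of strong (3x unitary) EPSGs both evoke spikes.
  With ``gna=None`` the delay-threshold curve over a bounded gNa sweep is
  minimized (the curve's left endpoint); with a fixed gNa the delay is
  measured at that conductance.
* :func:`parameter_space_sweep` — deterministic driver running any of the
  above over a coupling grid.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .channels import allocate_klt
from .dynamics import (
    DEFAULT_DT,
    SPIKE_DEAD_TIME,
    SPIKE_THRESHOLD,
    simulate,
)
from .params import (
    CouplingConfig,
    PassiveCellSpec,
    TwoCompartmentParams,
    build_two_compartment_params,
)
from .stimuli import Stimulus, phase_locked_trains

__all__ = [
    "KltSettings",
    "ProtocolResult",
    "apply_klt",
    "make_model",
    "find_gna_ref",
    "coincidence_sensitivity",
    "classify_firing_pattern",
    "find_gna_tonic",
    "ramp_threshold_gna",
    "delta_gna",
    "refractory_period",
    "delay_threshold_curve",
    "pair_response_h",
    "parameter_space_sweep",
]

#: Default EPSG onset used by the deterministic protocols, ms. Stimuli start
#: well after t=0 so any residual relaxation from the (exact) resting state
#: cannot contaminate the measurement.
ONSET = 5.0

#: gNa multiplier sweep for the coincidence protocol: 0.2 to 2.2 x gNa_ref
#: in increments of 0.05.
GNA_SWEEP = tuple(np.round(np.arange(0.2, 2.2001, 0.05), 10))

#: Bounded gNa sweep (in units of gNa_ref) searched by the delay-threshold
#: curve; the refractory period is the smallest delay at which a threshold
#: exists within this range.
REFRACTORY_GNA_RANGE = (0.2, 4.0)

#: Fixed step (ms) used for long stochastic firing-rate simulations; the
#: short deterministic threshold searches use the finer DEFAULT_DT.
RATE_DT = 1e-3


class ThresholdNotFoundError(RuntimeError):
    """A bisection target (spike threshold, tonic boundary) was not bracketed."""


@dataclass(frozen=True)
class KltSettings:
    """Allocation of low-threshold potassium conductance.

    ``placement`` selects the compartment(s) whose leak is partially
    replaced by KLT; ``fraction`` is the share of the resting conductance
    carried by KLT (default 10%); ``mode`` chooses frozen (KLT pinned at
    rest, equivalent to leak) or dynamic (voltage-gated) activation.
    """

    placement: str = "none"  # none | cpt1 | cpt2 | both
    fraction: float = 0.1
    mode: str = "frozen"

    def __post_init__(self) -> None:
        if self.placement not in ("none", "cpt1", "cpt2", "both"):
            raise ValueError(f"invalid KLT placement {self.placement!r}")
        if not 0.0 <= self.fraction < 1.0:
            raise ValueError("KLT fraction must lie in [0, 1)")
        if self.mode not in ("frozen", "dynamic"):
            raise ValueError("KLT mode must be 'frozen' or 'dynamic'")


FROZEN_KLT = KltSettings()


@dataclass(frozen=True)
class ProtocolResult:
    """Scalar outcome of one protocol at one coupling configuration."""

    coupling: CouplingConfig | None
    name: str
    value: float
    units: str
    se: float | None = None  # present iff the protocol is stochastic
    extras: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def apply_klt(params: TwoCompartmentParams, settings: KltSettings) -> TwoCompartmentParams:
    """Replace part of the leak by KLT conductance, preserving rest conductance."""
    g1, gk1 = params.g1, 0.0
    g2, gk2 = params.g2, 0.0
    if settings.placement in ("cpt1", "both"):
        g1, gk1 = allocate_klt(params.g1, settings.fraction, params.Vrest)
    if settings.placement in ("cpt2", "both"):
        g2, gk2 = allocate_klt(params.g2, settings.fraction, params.Vrest)
    return replace(params, g1=g1, g2=g2, gKLT1=gk1, gKLT2=gk2, klt_mode=settings.mode)


def make_model(
    spec: PassiveCellSpec,
    coupling: CouplingConfig,
    klt: KltSettings = FROZEN_KLT,
    gNa: float = 0.0,
) -> TwoCompartmentParams:
    """Convenience: passive construction + KLT allocation + sodium conductance."""
    p = build_two_compartment_params(spec, coupling)
    p = apply_klt(p, klt)
    return p.with_gna(gNa)


# ---------------------------------------------------------------------------
# Reference sodium conductance
# ---------------------------------------------------------------------------


def _spikes_single(params: TwoCompartmentParams, gna: float, scale: float, dt: float) -> int:
    r = simulate(
        params.with_gna(gna), Stimulus.epsg([(ONSET, scale)]), ONSET + 15.0, dt=dt
    )
    return r.n_spikes


def find_gna_ref(
    spec: PassiveCellSpec,
    coupling: CouplingConfig,
    klt: KltSettings = FROZEN_KLT,
    *,
    scale: float = 2.0,
    gna_bounds: tuple[float, float] = (1.0, 1e5),
    rel_tol: float = 0.005,
    dt: float = DEFAULT_DT,
) -> float:
    """Smallest gNa (nS) at which two simultaneous unitary EPSGs evoke a spike.

    Geometric bisection to a relative bracket width of ``rel_tol``; the
    returned value is the geometric midpoint of the final bracket, so
    simulating at (1 +/- 2*rel_tol) times the result flips the outcome.
    """
    params = make_model(spec, coupling, klt)
    lo, hi = gna_bounds
    if _spikes_single(params, hi, scale, dt) < 1:
        raise ThresholdNotFoundError(
            f"no spike at the upper gNa search bound {hi} nS for coupling {coupling}"
        )
    if _spikes_single(params, lo, scale, dt) >= 1:
        raise ThresholdNotFoundError(f"spike already at lower gNa bound {lo} nS")
    while hi / lo > 1.0 + rel_tol:
        mid = math.sqrt(lo * hi)
        if _spikes_single(params, mid, scale, dt) >= 1:
            hi = mid
        else:
            lo = mid
    return math.sqrt(lo * hi)


# ---------------------------------------------------------------------------
# Coincidence detection sensitivity (stochastic)
# ---------------------------------------------------------------------------


def _condition_stimuli(
    freq: float,
    side_delay: float,
    n_trials: int,
    duration: float,
    seed: int,
    condition_id: int,
) -> list[Stimulus]:
    """One afferent-ensemble stimulus per trial, independent substreams."""
    roots = np.random.SeedSequence([seed, condition_id]).generate_state(n_trials)
    return [
        phase_locked_trains(
            freq, duration, side_delay=side_delay, seed=int(roots[i])
        ).to_stimulus()
        for i in range(n_trials)
    ]


def _rates(
    params: TwoCompartmentParams,
    gna: float,
    stimuli: Sequence[Stimulus],
    duration: float,
    dt: float,
) -> tuple[float, float]:
    """Mean firing rate (sp/s) and its standard error over trials."""
    pg = params.with_gna(gna)
    counts = np.array(
        [simulate(pg, stim, duration, dt=dt).n_spikes for stim in stimuli], dtype=float
    )
    rates = counts / (duration / 1000.0)
    se = rates.std(ddof=1) / math.sqrt(len(rates)) if len(rates) > 1 else float("nan")
    return float(rates.mean()), float(se)


def coincidence_sensitivity(
    spec: PassiveCellSpec,
    coupling: CouplingConfig,
    freq: float,
    noncoincident_mode: str = "antiphase",
    klt: KltSettings = FROZEN_KLT,
    *,
    gna_sweep: Sequence[float] = GNA_SWEEP,
    n_trials: int = 100,
    duration: float = 250.0,
    seed: int = 0,
    gna_ref_value: float | None = None,
    dt: float = RATE_DT,
) -> ProtocolResult:
    """Maximum firing-rate difference (coincident - non-coincident) over a gNa sweep.

    The model is treated as an observer of its own inputs: the firing rate
    to coincident ensembles is the hit rate, the rate to non-coincident
    ensembles the false-alarm rate, and gNa plays the role of the decision
    threshold. Sensitivity is the largest rate difference attained across
    the sweep (multiples of gNa_ref).

    ``noncoincident_mode``: "antiphase" delays one ear by half the stimulus
    period; "delay_500us" uses a fixed 0.5 ms interaural delay.
    """
    if noncoincident_mode == "antiphase":
        nc_delay = 500.0 / freq  # half period in ms
    elif noncoincident_mode == "delay_500us":
        nc_delay = 0.5
    else:
        raise ValueError(f"unknown noncoincident_mode {noncoincident_mode!r}")

    params = make_model(spec, coupling, klt)
    if gna_ref_value is None:
        gna_ref_value = find_gna_ref(spec, coupling, klt)

    stim_c = _condition_stimuli(freq, 0.0, n_trials, duration, seed, condition_id=1)
    stim_n = _condition_stimuli(freq, nc_delay, n_trials, duration, seed, condition_id=2)

    rows = []
    for mult in gna_sweep:
        gna = mult * gna_ref_value
        rc, sec = _rates(params, gna, stim_c, duration, dt)
        rn, sen = _rates(params, gna, stim_n, duration, dt)
        rows.append(
            {
                "gna_mult": float(mult),
                "gna_nS": gna,
                "rate_coinc": rc,
                "se_coinc": sec,
                "rate_noncoinc": rn,
                "se_noncoinc": sen,
                "rate_diff": rc - rn,
                "se_diff": math.hypot(sec, sen),
            }
        )
    table = pd.DataFrame(rows)
    i_best = int(table["rate_diff"].idxmax())
    best = table.loc[i_best]
    return ProtocolResult(
        coupling=coupling,
        name="coincidence_sensitivity",
        value=float(best["rate_diff"]),
        units="spikes/s",
        se=float(best["se_diff"]),
        extras={
            "best_gna_mult": float(best["gna_mult"]),
            "best_gna_nS": float(best["gna_nS"]),
            "rate_coinc": float(best["rate_coinc"]),
            "rate_noncoinc": float(best["rate_noncoinc"]),
            "table": table,
        },
        provenance={
            "freq": freq,
            "mode": noncoincident_mode,
            "n_trials": n_trials,
            "duration": duration,
            "seed": seed,
            "gna_ref": gna_ref_value,
            "klt": klt,
        },
    )


# ---------------------------------------------------------------------------
# Tonic/phasic classification
# ---------------------------------------------------------------------------

PHASIC_WINDOW = 25.0  # ms after step onset within which phasic spikes must fall
TONIC_MIN_SPIKES = 5

#: Default amplitude grid for the tonic-boundary search (pA).
STEP_AMP_GRID = tuple(np.geomspace(100.0, 10000.0, 41))


def classify_firing_pattern(
    params: TwoCompartmentParams,
    gna: float,
    i_step: float,
    *,
    step_duration: float = 200.0,
    onset: float = ONSET,
    phasic_window: float = PHASIC_WINDOW,
    tonic_min_spikes: int = TONIC_MIN_SPIKES,
    dt: float = RATE_DT,
) -> str:
    """Label the step response: 'quiescent', 'phasic', or 'tonic'.

    Tonic means sustained firing: at least ``tonic_min_spikes`` spikes with
    the last one in the final third of the step. Phasic means firing
    confined to the onset transient (``phasic_window`` ms). Sparse spiking
    that dies out between the onset window and the final third is grouped
    with phasic (it is not sustained).
    """
    r = simulate(
        params.with_gna(gna),
        Stimulus.step(i_step, onset, step_duration),
        onset + step_duration + 5.0,
        dt=dt,
    )
    st = r.spike_times
    if len(st) == 0:
        return "quiescent"
    if len(st) >= tonic_min_spikes and st[-1] >= onset + 2.0 * step_duration / 3.0:
        return "tonic"
    return "phasic"


def find_gna_tonic(
    spec: PassiveCellSpec,
    coupling: CouplingConfig,
    klt: KltSettings = FROZEN_KLT,
    *,
    gna_ref_value: float | None = None,
    amp_grid: Sequence[float] = STEP_AMP_GRID,
    ratio_bounds: tuple[float, float] = (0.2, 8.0),
    n_scan: int = 25,
    rel_tol: float = 0.02,
    dt: float = RATE_DT,
) -> ProtocolResult:
    """Smallest gNa admitting tonic firing at any step amplitude.

    The tonic region in the (I_step, gNa) plane is bounded: it closes from
    below (insufficient sodium) and, at large gNa, firing gives way to
    depolarization block. The lower boundary is located by an ascending
    geometric scan of gNa (in units of gNa_ref) over the amplitude grid,
    then bisection between the last all-phasic and first tonic gNa.
    """
    params = make_model(spec, coupling, klt)
    if gna_ref_value is None:
        gna_ref_value = find_gna_ref(spec, coupling, klt)

    def any_tonic(gna: float) -> bool:
        return any(
            classify_firing_pattern(params, gna, amp, dt=dt) == "tonic" for amp in amp_grid
        )

    scan = np.geomspace(ratio_bounds[0], ratio_bounds[1], n_scan)
    first = None
    prev = None
    for ratio in scan:
        if any_tonic(ratio * gna_ref_value):
            first = ratio
            break
        prev = ratio
    if first is None:
        raise ThresholdNotFoundError(
            f"no tonic firing for gNa up to {ratio_bounds[1]:.2f} x gNa_ref "
            f"({ratio_bounds[1] * gna_ref_value:.0f} nS) for coupling {coupling}"
        )
    if prev is None:  # tonic already at the lower scan bound
        lo, hi = first * 0.5, first
    else:
        lo, hi = prev, first
    lo *= gna_ref_value
    hi *= gna_ref_value
    while hi / lo > 1.0 + rel_tol:
        mid = math.sqrt(lo * hi)
        if any_tonic(mid):
            hi = mid
        else:
            lo = mid
    gna_tonic = math.sqrt(lo * hi)
    return ProtocolResult(
        coupling=coupling,
        name="gna_tonic",
        value=gna_tonic,
        units="nS",
        extras={"ratio": gna_tonic / gna_ref_value, "gna_ref": gna_ref_value},
        provenance={"amp_grid": list(amp_grid), "ratio_bounds": ratio_bounds, "klt": klt},
    )


# ---------------------------------------------------------------------------
# Slope sensitivity
# ---------------------------------------------------------------------------


def ramp_threshold_gna(
    spec: PassiveCellSpec,
    coupling: CouplingConfig,
    slope: float,
    peak: float = 2500.0,
    klt: KltSettings = FROZEN_KLT,
    *,
    gna_bounds: tuple[float, float] = (1.0, 1e6),
    rel_tol: float = 0.005,
    dt: float = DEFAULT_DT,
) -> float:
    """Smallest gNa (nS) at which a current ramp of given slope evokes a spike."""
    if slope <= 0:
        raise ValueError("ramp slope must be positive")
    params = make_model(spec, coupling, klt)
    t_end = ONSET + peak / slope + 20.0

    def spikes(gna: float) -> int:
        r = simulate(params.with_gna(gna), Stimulus.ramp(slope, peak, ONSET), t_end, dt=dt)
        return r.n_spikes

    lo, hi = gna_bounds
    if spikes(hi) < 1:
        raise ThresholdNotFoundError(f"no spike at upper gNa bound {hi} nS (slope {slope})")
    if spikes(lo) >= 1:
        raise ThresholdNotFoundError(f"spike already at lower gNa bound {lo} nS")
    while hi / lo > 1.0 + rel_tol:
        mid = math.sqrt(lo * hi)
        if spikes(mid) >= 1:
            hi = mid
        else:
            lo = mid
    return math.sqrt(lo * hi)


def delta_gna(
    spec: PassiveCellSpec,
    coupling: CouplingConfig,
    klt: KltSettings = FROZEN_KLT,
    *,
    slow_slope: float = 500.0,
    fast_slope: float = 1000.0,
    peak: float = 2500.0,
    dt: float = DEFAULT_DT,
) -> ProtocolResult:
    """Slope sensitivity: threshold-gNa ratio for slow vs fast current ramps.

    Values near 1 mean the neuron fires at similar gNa regardless of input
    slope; values well above 1 mean slow ramps require much more sodium
    conductance, i.e. the neuron selectively fires to fast-rising inputs.
    """
    thr_slow = ramp_threshold_gna(spec, coupling, slow_slope, peak, klt, dt=dt)
    thr_fast = ramp_threshold_gna(spec, coupling, fast_slope, peak, klt, dt=dt)
    return ProtocolResult(
        coupling=coupling,
        name="delta_gna",
        value=thr_slow / thr_fast,
        units="",
        extras={"thr_slow_nS": thr_slow, "thr_fast_nS": thr_fast},
        provenance={"slow_slope": slow_slope, "fast_slope": fast_slope, "peak": peak},
    )


# ---------------------------------------------------------------------------
# Refractory period
# ---------------------------------------------------------------------------


def _both_events_fire(
    params: TwoCompartmentParams,
    gna: float,
    delay: float,
    scale: float,
    dt: float,
) -> bool:
    """True iff each EPSG of the pair evokes its own spike.

    Requires a spike in [t1, t2) and a spike at/after t2, with the control
    that a single event at this gNa evokes exactly one spike (excluding
    conductances so high that one event alone fires repetitively, in which
    case a second spike cannot be attributed to the trailing event).
    """
    t1 = ONSET
    t2 = ONSET + delay
    pg = params.with_gna(gna)
    r = simulate(pg, Stimulus.epsg([(t1, scale), (t2, scale)]), t2 + 15.0, dt=dt)
    st = r.spike_times
    if not (np.any((st >= t1) & (st < t2)) and np.any(st >= t2)):
        return False
    r1 = simulate(pg, Stimulus.epsg([(t1, scale)]), t2 + 15.0, dt=dt)
    return r1.n_spikes == 1


def _threshold_on_grid(
    params: TwoCompartmentParams,
    gna_grid: np.ndarray,
    delay: float,
    scale: float,
    dt: float,
) -> float | None:
    """Smallest gNa on an ascending grid for which both events fire."""
    for gna in gna_grid:
        if _both_events_fire(params, gna, delay, scale, dt):
            return float(gna)
    return None


def delay_threshold_curve(
    spec: PassiveCellSpec,
    coupling: CouplingConfig,
    klt: KltSettings = FROZEN_KLT,
    *,
    delays: Sequence[float] = tuple(np.arange(0.5, 3.01, 0.25)),
    epsg_scale: float = 3.0,
    gna_range: tuple[float, float] = REFRACTORY_GNA_RANGE,
    n_gna: int = 41,
    gna_ref_value: float | None = None,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Threshold gNa (units of gNa_ref) for both EPSGs to fire, per delay.

    Thresholds are searched on a geometric grid spanning ``gna_range`` x
    gNa_ref; delays with no threshold in range get NaN. The curve is
    nonincreasing over the delays where it is defined.
    """
    params = make_model(spec, coupling, klt)
    if gna_ref_value is None:
        gna_ref_value = find_gna_ref(spec, coupling, klt)
    grid = np.geomspace(gna_range[0], gna_range[1], n_gna) * gna_ref_value
    rows = []
    for d in delays:
        thr = _threshold_on_grid(params, grid, float(d), epsg_scale, dt)
        rows.append(
            {
                "delay_ms": float(d),
                "threshold_gna_nS": thr if thr is not None else float("nan"),
                "threshold_gna_mult": (thr / gna_ref_value) if thr is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def refractory_period(
    spec: PassiveCellSpec,
    coupling: CouplingConfig,
    klt: KltSettings = FROZEN_KLT,
    *,
    gna: float | None = None,
    epsg_scale: float = 3.0,
    delay_range: tuple[float, float] = (0.1, 5.0),
    delay_tol: float = 0.01,
    gna_range: tuple[float, float] = REFRACTORY_GNA_RANGE,
    n_gna: int = 41,
    gna_ref_value: float | None = None,
    dt: float = DEFAULT_DT,
) -> ProtocolResult:
    """Minimum delay at which both strong (3x unitary) EPSGs evoke spikes.

    With ``gna=None`` (default) the measure is the left endpoint of the
    delay-threshold curve: the smallest delay at which *some* gNa within
    ``gna_range`` x gNa_ref lets both events fire. With a fixed ``gna``
    (nS) the delay is measured at that conductance only.
    """
    params = make_model(spec, coupling, klt)
    if gna_ref_value is None:
        gna_ref_value = find_gna_ref(spec, coupling, klt)

    if gna is None:
        grid = np.geomspace(gna_range[0], gna_range[1], n_gna) * gna_ref_value

        def fires(delay: float) -> bool:
            return _threshold_on_grid(params, grid, delay, epsg_scale, dt) is not None

    else:

        def fires(delay: float) -> bool:
            return _both_events_fire(params, gna, delay, epsg_scale, dt)

    lo, hi = delay_range
    if not fires(hi):
        raise ThresholdNotFoundError(
            f"no double-spike response even at {hi} ms delay for coupling {coupling}"
        )
    if fires(lo):
        rp = lo
    else:
        while hi - lo > delay_tol:
            mid = 0.5 * (lo + hi)
            if fires(mid):
                hi = mid
            else:
                lo = mid
        rp = 0.5 * (lo + hi)
    return ProtocolResult(
        coupling=coupling,
        name="refractory_period",
        value=rp,
        units="ms",
        extras={"gna_ref": gna_ref_value, "gna_fixed": gna},
        provenance={
            "epsg_scale": epsg_scale,
            "gna_range": None if gna is not None else gna_range,
            "klt": klt,
        },
    )


def pair_response_h(
    spec: PassiveCellSpec,
    coupling: CouplingConfig,
    klt: KltSettings = FROZEN_KLT,
    *,
    delay: float = 1.5,
    at: float = 1.5,
    epsg_scale: float = 3.0,
    gna: float | None = None,
    dt: float = DEFAULT_DT,
) -> float:
    """Sodium inactivation h at ``at`` ms after the first of two EPSGs.

    Exposes the post-spike recovery state that distinguishes coupling
    configurations in the V2-h phase plane (gna defaults to gNa_ref).
    """
    params = make_model(spec, coupling, klt)
    if gna is None:
        gna = find_gna_ref(spec, coupling, klt)
    stim = Stimulus.epsg([(ONSET, epsg_scale), (ONSET + delay, epsg_scale)])
    r = simulate(params.with_gna(gna), stim, ONSET + delay + 15.0, dt=dt)
    return r.state_at(ONSET + at).h


# ---------------------------------------------------------------------------
# Sweep driver
# ---------------------------------------------------------------------------


def _cell_key(name: str, coupling: CouplingConfig, settings: dict) -> str:
    blob = json.dumps(
        {"protocol": name, "kf": coupling.kappa_fwd, "kb": coupling.kappa_back, **settings},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def parameter_space_sweep(
    protocol: Callable[..., ProtocolResult],
    grid: Sequence[CouplingConfig],
    spec: PassiveCellSpec,
    settings: dict | None = None,
    cache_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run a protocol over a coupling grid; one row per configuration.

    Deterministic ordering (the grid's). Per-cell failures are recorded in
    the ``error`` column rather than aborting the sweep. With ``cache_dir``
    set, each cell's result is stored as JSON keyed by (protocol, coupling,
    settings) so interrupted sweeps can resume.
    """
    settings = dict(settings or {})
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    for cc in grid:
        row: dict = {"kappa_fwd": cc.kappa_fwd, "kappa_back": cc.kappa_back}
        key = _cell_key(getattr(protocol, "__name__", str(protocol)), cc, settings)
        cfile = cache / f"{key}.json" if cache is not None else None
        if cfile is not None and cfile.exists():
            row.update(json.loads(cfile.read_text()))
            rows.append(row)
            continue
        try:
            res = protocol(spec, cc, **settings)
            cell = {"value": res.value, "units": res.units, "se": res.se, "error": ""}
            for k, v in res.extras.items():
                if isinstance(v, (int, float, str)):
                    cell[k] = v
        except Exception as exc:  # noqa: BLE001 - per-cell failures are data
            cell = {"value": float("nan"), "units": "", "se": None, "error": str(exc)}
        if cfile is not None:
            cfile.write_text(json.dumps(cell))
        row.update(cell)
        rows.append(row)
    return pd.DataFrame(rows)
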