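"""Integration of the full system: rest invariance, passive behaviour,
engine-vs-reference agreement, and spike detection."""

import numpy as np
import pytest

from twocpt import (
    CouplingConfig,
    MSO_SPEC,
    WEAKLY_COUPLED,
    build_two_compartment_params,
)
from twocpt.dynamics import (
    CellState,
    derivatives,
    detect_spikes,
    resting_state,
    simulate,
)
from twocpt.protocols import KltSettings, apply_klt, make_model
from twocpt.stimuli import Stimulus


def test_rest_is_exact_equilibrium(named_params):
    """With the rest-correction terms, rest is an equilibrium of the full system."""
    for p in named_params.values():
        active = apply_klt(p, KltSettings("both", 0.1, "dynamic")).with_gna(2000.0)
        d = derivatives(resting_state(active), 0.0, active, Stimulus.zero())
        assert np.linalg.norm(d) < 1e-12


def test_zero_stimulus_stays_flat(named_params):
    r = simulate(named_params["weak"], Stimulus.zero(), 20.0, dt=1e-3)
    assert np.allclose(r.V1, -58.0, atol=1e-9)
    assert np.allclose(r.V2, -58.0, atol=1e-9)
    assert r.n_spikes == 0


def test_passive_steady_state_attenuation_is_kappa_fwd(spec):
    """Constant current into Cpt1: U2/U1 settles to kappa_fwd."""
    for kf, kb in [(0.3, 0.2), (0.8, 0.2), (0.8, 0.7)]:
        p = build_two_compartment_params(spec, CouplingConfig(kf, kb))
        r = simulate(p, Stimulus.step(500.0, 2.0, 30.0), 25.0, dt=1e-3)
        u1 = r.V1[-1] - p.Elk
        u2 = r.V2[-1] - p.Elk
        assert u2 / u1 == pytest.approx(kf, rel=1e-3)


def test_passive_steady_state_backward_ratio_is_kappa_back(spec):
    """Constant current into Cpt2 (steady-state solve): U1/U2 = kappa_back."""
    for kf, kb in [(0.3, 0.2), (0.8, 0.7)]:
        p = build_two_compartment_params(spec, CouplingConfig(kf, kb))
        A = np.array([[p.g1 + p.gc, -p.gc], [-p.gc, p.g2 + p.gc]])
        u = np.linalg.solve(A, [0.0, 100.0])
        assert u[0] / u[1] == pytest.approx(kb, rel=1e-9)


def test_unitary_epsg_depolarizes_v1_about_6mv(named_params):
    r = simulate(named_params["weak"], Stimulus.epsg([(5.0, 1.0)]), 15.0)
    assert r.V1.max() - (-58.0) == pytest.approx(6.0, abs=1.0)


def test_passive_v1_invariance_across_named_models(named_params):
    """V1 responses to the same EPSG are near-identical across couplings."""
    traces = {}
    for k, p in named_params.items():
        r = simulate(p, Stimulus.epsg([(5.0, 1.0)]), 15.0, dt=2.5e-4)
        traces[k] = r.V1
    peak = traces["weak"].max() - (-58.0)
    for k in ("forward", "strong"):
        assert np.max(np.abs(traces[k] - traces["weak"])) < 0.02 * peak


def test_frozen_klt_matches_passive_model(spec):
    """Frozen KLT re-partitions leak without changing subthreshold dynamics."""
    p = build_two_compartment_params(spec, WEAKLY_COUPLED)
    pk = apply_klt(p, KltSettings("both", 0.1, "frozen"))
    stim = Stimulus.epsg([(2.0, 1.0)])
    r0 = simulate(p, stim, 12.0, dt=2.5e-4)
    r1 = simulate(pk, stim, 12.0, dt=2.5e-4)
    assert np.max(np.abs(r0.V1 - r1.V1)) < 1e-9
    assert np.max(np.abs(r0.V2 - r1.V2)) < 1e-9


def test_simulation_deterministic(named_params, gna_refs):
    p = named_params["forward"].with_gna(gna_refs["forward"])
    stim = Stimulus.epsg([(5.0, 2.0)])
    a = simulate(p, stim, 20.0)
    b = simulate(p, stim, 20.0)
    np.testing.assert_array_equal(a.V2, b.V2)
    np.testing.assert_array_equal(a.spike_times, b.spike_times)


def test_spike_times_stable_under_step_halving(named_params, gna_refs):
    """Halving the integration step moves spike times by < 1 us
    on the paired-EPSG protocol."""
    p = named_params["forward"].with_gna(gna_refs["forward"])
    stim = Stimulus.epsg([(5.0, 3.0), (7.5, 3.0)])
    a = simulate(p, stim, 20.0, dt=1e-4)
    b = simulate(p, stim, 20.0, dt=5e-5)
    assert a.n_spikes == b.n_spikes == 2
    assert np.max(np.abs(a.spike_times - b.spike_times)) < 1e-3  # ms


def test_engine_agrees_with_stiff_reference_solver(named_params, gna_refs):
    """The compiled engine and the variable-step stiff solver agree on the
    spike raster and times for an active paired-EPSG response."""
    p = named_params["weak"].with_gna(gna_refs["weak"])
    stim = Stimulus.epsg([(5.0, 3.0), (7.5, 3.0)])
    a = simulate(p, stim, 20.0, dt=1e-4)
    b = simulate(p, stim, 20.0, method="lsoda", rtol=1e-8, atol=1e-10)
    assert a.n_spikes == b.n_spikes
    assert np.max(np.abs(a.spike_times - b.spike_times)) < 0.01  # ms


def test_engine_step_matches_rhs_to_first_order(named_params):
    """One tiny engine step equals state + dt * RHS up to O(dt^2)."""
    p = apply_klt(named_params["strong"], KltSettings("cpt2", 0.1, "dynamic")).with_gna(500.0)
    init = CellState(-52.0, -47.0, 0.3, 0.6, 0.55)
    dt = 1e-6
    r = simulate(p, Stimulus.zero(), 10 * dt, dt=dt, record_dt=dt, initial=init)
    d = derivatives(init, 0.0, p, Stimulus.zero())
    one_step = np.array(init) + dt * d
    got = np.array([r.V1[1], r.V2[1], r.h[1], r.w1[1], r.w2[1]])
    np.testing.assert_allclose(got, one_step, rtol=1e-6, atol=1e-7)


def test_detect_spikes_cases():
    t = np.linspace(0.0, 20.0, 2001)
    flat = np.full_like(t, -58.0)
    assert detect_spikes(t, flat).size == 0
    # sawtooth crossing -20 twice, 5 ms apart
    saw = -60.0 + 50.0 * ((t % 5.0) / 5.0)
    st = detect_spikes(t, saw, threshold=-20.0, dead_time=0.5)
    assert len(st) == 4  # one upward crossing per 5 ms period
    assert np.all(np.diff(st) >= 0.5)
    # subthreshold bump
    bump = -58.0 + 28.0 * np.exp(-((t - 10.0) ** 2))
    assert detect_spikes(t, bump, threshold=-20.0).size == 0


def test_detect_spikes_interpolates_crossing_time():
    t = np.array([0.0, 1.0, 2.0])
    v = np.array([-40.0, -10.0, -40.0])
    st = detect_spikes(t, v, threshold=-20.0)
    assert st == pytest.approx([2.0 / 3.0])


def test_simulate_validates_duration(named_params):
    with pytest.raises(ValueError):
        simulate(named_params["weak"], Stimulus.zero(), -1.0)


def test_resting_state_components(named_params):
    rs = resting_state(named_params["weak"])
    assert rs.V1 == rs.V2 == -58.0
    assert rs.h == pytest.approx(0.2376, abs=1e-3)
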