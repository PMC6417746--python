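"""Stimulus kernels, waveforms, and the synthetic afferent generator."""

import numpy as np
import pytest

from twocpt import stimuli as stim


def test_epsg_kernel_causal_and_zero_at_onset():
    assert stim.epsg_kernel(0.0) == 0.0
    assert stim.epsg_kernel(-1.0) == 0.0
    assert np.all(np.asarray(stim.epsg_kernel(np.linspace(-2, 0, 10))) == 0.0)


def test_epsg_kernel_peak_closed_form():
    t_pk, g_pk = stim.epsg_peak()
    assert t_pk == pytest.approx(0.1323, abs=2e-4)
    assert g_pk == pytest.approx(26.70, abs=0.02)
    # the sampled kernel never exceeds the closed-form peak
    t = np.linspace(0.0, 3.0, 30001)
    assert np.max(stim.epsg_kernel(t)) <= g_pk + 1e-12


def test_conductance_train_superposition():
    t = np.linspace(0.0, 5.0, 501)
    one = stim.conductance_train([(1.0, 1.0)])(t)
    np.testing.assert_allclose(one, stim.epsg_kernel(t - 1.0))
    double = stim.conductance_train([(1.0, 1.0), (1.0, 1.0)])(t)
    np.testing.assert_allclose(double, 2 * one)
    scaled = stim.conductance_train([(1.0, 3.0)])(t)
    np.testing.assert_allclose(scaled, 3 * one)


def test_step_current_waveform():
    i = stim.step_current(2500.0, onset=5.0, duration=200.0)
    assert i(4.999) == 0.0
    assert i(5.0) == 2500.0
    assert i(100.0) == 2500.0
    assert i(205.1) == 0.0
    assert stim.step_current(0.0, 5.0, 10.0)(7.0) == 0.0


def test_ramp_current_waveform():
    i = stim.ramp_current(1000.0, peak=2500.0, onset=5.0)
    assert i(5.0) == 0.0
    assert i(7.5) == pytest.approx(2500.0)
    assert i(6.0) == pytest.approx(1000.0)
    assert i(20.0) == 2500.0  # sustained at peak
    i2 = stim.ramp_current(500.0, peak=2500.0, onset=5.0)
    assert i2(10.0) == pytest.approx(2500.0)
    with pytest.raises(ValueError):
        stim.ramp_current(-1.0, 2500.0, 5.0)


def test_stimulus_piecewise_current_matches_callables():
    s = stim.Stimulus.step(1000.0, onset=5.0, duration=10.0)
    assert s.i_app(4.0) == 0.0
    assert s.i_app(10.0) == 1000.0
    assert s.i_app(16.0) == 0.0
    r = stim.Stimulus.ramp(500.0, peak=2500.0, onset=5.0)
    assert r.i_app(6.0) == pytest.approx(500.0)
    assert r.i_app(30.0) == 2500.0


def test_trains_deterministic_given_seed():
    a = stim.phase_locked_trains(500.0, 500.0, seed=42)
    b = stim.phase_locked_trains(500.0, 500.0, seed=42)
    for fa, fb in zip(a.fibers, b.fibers):
        np.testing.assert_array_equal(fa, fb)
    c = stim.phase_locked_trains(500.0, 500.0, seed=43)
    assert any(len(x) != len(y) or not np.array_equal(x, y) for x, y in zip(a.fibers, c.fibers))


def test_trains_respect_refractory_gap():
    tr = stim.phase_locked_trains(500.0, 2000.0, seed=3)
    for f in tr.fibers:
        if len(f) > 1:
            assert np.min(np.diff(f)) >= tr.refractory


def test_train_mean_rate_near_target():
    """Empirical rate of one fiber over 10 s within 3 SE of the 200 sp/s target."""
    tr = stim.phase_locked_trains(500.0, 10_000.0, seed=11)
    n = len(tr.side_a[0])
    rate = n / 10.0
    se = np.sqrt(n) / 10.0
    assert abs(rate - tr.mean_rate) < 3 * se


def test_train_vector_strength_near_target():
    tr = stim.phase_locked_trains(500.0, 10_000.0, seed=11)
    spikes = np.concatenate([f for f in tr.fibers])
    vs = stim.vector_strength(spikes, 500.0)
    assert vs == pytest.approx(tr.vs_target, abs=0.05)


def test_vs_targets_decline_with_frequency():
    targets = [stim.vs_target_for_freq(f) for f in (200, 300, 400, 500, 600, 700)]
    assert targets == sorted(targets, reverse=True)
    assert stim.vs_target_for_freq(250) == pytest.approx(0.775)


def test_side_delay_shifts_phase():
    """Delayed ear phase-locks at a shifted phase, same lock strength."""
    f = 500.0
    coin = stim.phase_locked_trains(f, 10_000.0, side_delay=0.0, seed=5)
    anti = stim.phase_locked_trains(f, 10_000.0, side_delay=1.0, seed=5)  # half period
    pha = np.angle(np.mean(np.exp(1j * 2 * np.pi * f * np.concatenate(coin.side_b) / 1000.0)))
    phb = np.angle(np.mean(np.exp(1j * 2 * np.pi * f * np.concatenate(anti.side_b) / 1000.0)))
    dphi = np.angle(np.exp(1j * (phb - pha)))
    assert abs(abs(dphi) - np.pi) < 0.15


def test_bad_train_arguments():
    with pytest.raises(ValueError):
        stim.phase_locked_trains(500.0, -1.0, seed=0)
    with pytest.raises(ValueError):
        stim.phase_locked_trains(500.0, 100.0, mean_rate=0.0, seed=0)
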