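"""Measurement protocols: threshold searches, classification, sweeps."""

import numpy as np
import pandas as pd
import pytest

from twocpt import CouplingConfig, MSO_SPEC
from twocpt.protocols import (
    KltSettings,
    ThresholdNotFoundError,
    _rates,
    _condition_stimuli,
    apply_klt,
    classify_firing_pattern,
    find_gna_ref,
    make_model,
    parameter_space_sweep,
    refractory_period,
    ProtocolResult,
)
from twocpt.dynamics import simulate
from twocpt.stimuli import Stimulus


def test_gna_ref_bracket_is_validated(named_params, gna_refs):
    """Simulating 2% either side of the returned threshold flips the outcome."""
    for name, g in gna_refs.items():
        p = named_params[name]
        stim = Stimulus.epsg([(5.0, 2.0)])
        assert simulate(p.with_gna(1.02 * g), stim, 20.0).n_spikes >= 1
        assert simulate(p.with_gna(0.98 * g), stim, 20.0).n_spikes == 0


def test_gna_ref_error_when_unreachable(spec):
    with pytest.raises(ThresholdNotFoundError):
        find_gna_ref(spec, CouplingConfig(0.3, 0.2), gna_bounds=(1.0, 10.0))


def test_klt_allocation_preserves_passive_construction(spec):
    """KLT splitting keeps total resting conductance of each compartment."""
    from twocpt import build_two_compartment_params
    from twocpt.channels import w_inf, z_inf

    p0 = build_two_compartment_params(spec, CouplingConfig(0.8, 0.2))
    p1 = apply_klt(p0, KltSettings("both", 0.1, "dynamic"))
    wz = float(w_inf(p0.Vrest)) ** 4 * float(z_inf(p0.Vrest))
    assert p1.g1 + p1.gKLT1 * wz == pytest.approx(p0.g1, rel=1e-12)
    assert p1.g2 + p1.gKLT2 * wz == pytest.approx(p0.g2, rel=1e-12)


def test_classify_quiescent_without_sodium(spec):
    p = make_model(spec, CouplingConfig(0.3, 0.2))
    assert classify_firing_pattern(p, 0.0, 3000.0) == "quiescent"


def test_classify_named_models_at_reference(named_params, gna_refs):
    """At gNa_ref a suprathreshold step drives the weakly-coupled model
    tonically but the forward-coupled model only phasically."""
    labels_weak = {
        classify_firing_pattern(named_params["weak"], gna_refs["weak"], a)
        for a in (3000.0, 5000.0)
    }
    assert "tonic" in labels_weak
    for a in (1000.0, 2500.0, 5000.0, 8000.0):
        assert (
            classify_firing_pattern(named_params["forward"], gna_refs["forward"], a)
            != "tonic"
        )


def test_refractory_fixed_gna_matches_example_traces(spec, gna_refs):
    """At gNa_ref the weakly-coupled model recovers between 2 and 2.5 ms,
    the forward-coupled by 1.5 ms, the strongly-coupled by 2 ms."""
    rp_weak = refractory_period(
        spec, CouplingConfig(0.3, 0.2), gna=gna_refs["weak"], gna_ref_value=gna_refs["weak"]
    ).value
    assert 2.0 < rp_weak <= 2.5
    rp_fwd = refractory_period(
        spec, CouplingConfig(0.8, 0.2), gna=gna_refs["forward"], gna_ref_value=gna_refs["forward"]
    ).value
    assert rp_fwd <= 1.5
    rp_strong = refractory_period(
        spec, CouplingConfig(0.8, 0.7), gna=gna_refs["strong"], gna_ref_value=gna_refs["strong"]
    ).value
    assert 1.5 < rp_strong <= 2.0


def test_rate_se_scales_with_trial_count(spec, gna_refs):
    """Standard error of the firing rate shrinks like 1/sqrt(n_trials)."""
    p = make_model(spec, CouplingConfig(0.8, 0.2), gNa=gna_refs["forward"])
    stims = _condition_stimuli(500.0, 0.0, 100, 100.0, seed=9, condition_id=1)
    _, se100 = _rates(p, gna_refs["forward"], stims, 100.0, dt=1e-3)
    _, se25 = _rates(p, gna_refs["forward"], stims[:25], 100.0, dt=1e-3)
    assert se25 / se100 == pytest.approx(2.0, rel=0.5)


def test_sweep_table_deterministic_and_complete(spec):
    grid = [CouplingConfig(0.3, 0.2), CouplingConfig(0.8, 0.2)]

    def gnaref_protocol(s, cc, **kw):
        return ProtocolResult(cc, "gna_ref", find_gna_ref(s, cc), "nS")

    t1 = parameter_space_sweep(gnaref_protocol, grid, spec)
    t2 = parameter_space_sweep(gnaref_protocol, grid, spec)
    pd.testing.assert_frame_equal(t1, t2)
    assert list(t1["kappa_fwd"]) == [0.3, 0.8]
    assert (t1["error"] == "").all()


def test_sweep_empty_grid_and_failures(spec):
    def failing(s, cc, **kw):
        raise RuntimeError("boom")

    empty = parameter_space_sweep(failing, [], spec)
    assert len(empty) == 0
    t = parameter_space_sweep(failing, [CouplingConfig(0.3, 0.2)], spec)
    assert t.loc[0, "error"] == "boom"
    assert np.isnan(t.loc[0, "value"])


def test_sweep_cache_resumes(tmp_path, spec):
    calls = []

    def counting(s, cc, **kw):
        calls.append(cc)
        return ProtocolResult(cc, "x", 1.0, "")

    grid = [CouplingConfig(0.3, 0.2)]
    parameter_space_sweep(counting, grid, spec, cache_dir=tmp_path)
    parameter_space_sweep(counting, grid, spec, cache_dir=tmp_path)
    assert len(calls) == 1
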