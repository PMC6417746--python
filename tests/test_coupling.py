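"""Passive construction: coupling parameterization and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twocpt import (
    CouplingConfig,
    MSO_SPEC,
    PassiveCellSpec,
    build_two_compartment_params,
    coupling_from_conductances,
    coupling_grid,
    timescale_ratio,
)
from twocpt.params import CouplingError


def valid_pairs():
    """Coupling pairs satisfying the model's wedge constraints."""
    return (
        st.tuples(
            st.floats(0.05, 0.95, allow_nan=False),
            st.floats(0.05, 0.95, allow_nan=False),
        )
        .map(lambda t: (max(t), min(t)))
        .filter(lambda t: t[0] / t[1] <= 10.0 and t[0] * t[1] < 1.0)
    )


@pytest.mark.parametrize(
    "kf, kb, g1, g2, gc",
    [
        (0.3, 0.2, 100.1, 58.41, 25.03),  # hand-evaluated from the closed form
        (0.8, 0.2, 112.0, 7.00, 28.01),
    ],
)
def test_construction_matches_hand_evaluation(kf, kb, g1, g2, gc):
    p = build_two_compartment_params(MSO_SPEC, CouplingConfig(kf, kb))
    assert p.g1 == pytest.approx(g1, rel=1e-3)
    assert p.g2 == pytest.approx(g2, rel=1e-3)
    assert p.gc == pytest.approx(gc, rel=1e-3)
    assert p.c2 == pytest.approx(MSO_SPEC.alpha * p.c1)


@given(valid_pairs())
@settings(max_examples=100, deadline=None)
def test_c1_is_tau_over_rin_for_all_couplings(pair):
    """c1 = tau_exp/Rin is an algebraic identity, independent of coupling."""
    p = build_two_compartment_params(MSO_SPEC, CouplingConfig(*pair))
    assert p.c1 == pytest.approx(1000.0 * MSO_SPEC.tau_exp / MSO_SPEC.Rin, rel=1e-12)


@given(valid_pairs())
@settings(max_examples=100, deadline=None)
def test_coupling_roundtrip(pair):
    """Conductances -> coupling inverts the construction to 1e-10."""
    p = build_two_compartment_params(MSO_SPEC, CouplingConfig(*pair))
    kf, kb = coupling_from_conductances(p.g1, p.g2, p.gc)
    assert kf == pytest.approx(pair[0], abs=1e-10)
    assert kb == pytest.approx(pair[1], abs=1e-10)


@given(valid_pairs())
@settings(max_examples=100, deadline=None)
def test_analytic_input_resistance(pair):
    """Steady-state 2x2 solve gives U1/I = Rin for every configuration."""
    p = build_two_compartment_params(MSO_SPEC, CouplingConfig(*pair))
    A = np.array([[p.g1 + p.gc, -p.gc], [-p.gc, p.g2 + p.gc]])
    i_in = 100.0  # pA into Cpt1
    u = np.linalg.solve(A, [i_in, 0.0])
    rin_mohm = 1000.0 * u[0] / i_in  # mV/pA -> MOhm via nS units
    assert abs(rin_mohm - MSO_SPEC.Rin) / MSO_SPEC.Rin < 1e-9


def test_coupling_from_conductances_limits():
    assert coupling_from_conductances(100.0, 50.0, 0.0) == (0.0, 0.0)
    kf, _ = coupling_from_conductances(100.0, 0.0, 30.0)
    assert kf == 1.0
    with pytest.raises(ZeroDivisionError):
        coupling_from_conductances(0.0, 50.0, 0.0)


@pytest.mark.parametrize(
    "kf, kb",
    [(1.0, 1.0), (0.2, 0.3), (0.9, 0.05), (0.0, 0.0), (1.2, 0.5)],
)
def test_invalid_couplings_rejected(kf, kb):
    with pytest.raises(CouplingError):
        CouplingConfig(kf, kb)


def test_timescale_ratio():
    assert timescale_ratio(MSO_SPEC, CouplingConfig(0.3, 0.2)) == pytest.approx(0.015)
    assert timescale_ratio(MSO_SPEC, CouplingConfig(0.8, 0.2)) == pytest.approx(0.04)
    assert timescale_ratio(MSO_SPEC, CouplingConfig(0.5, 0.5)) == pytest.approx(0.01)


def test_timescale_ratio_matches_constructed_taus():
    p = build_two_compartment_params(MSO_SPEC, CouplingConfig(0.8, 0.2))
    assert p.epsilon == pytest.approx(timescale_ratio(MSO_SPEC, p.coupling), rel=1e-12)


def test_grid_constraints_and_ordering():
    grid = coupling_grid(step=0.05, bounds=(0.1, 0.9))
    assert all(cc.kappa_fwd >= cc.kappa_back for cc in grid)
    assert all(cc.kappa_fwd / cc.kappa_back <= 10.0 + 1e-9 for cc in grid)
    # row-major ordering: kappa_back slow axis
    kbs = [cc.kappa_back for cc in grid]
    assert kbs == sorted(kbs)
    # the three named configurations are on the default grid
    pts = {(round(cc.kappa_fwd, 3), round(cc.kappa_back, 3)) for cc in grid}
    assert {(0.3, 0.2), (0.8, 0.2), (0.8, 0.7)} <= pts


def test_grid_empty_bounds_error():
    with pytest.raises(ValueError):
        coupling_grid(step=0.1, bounds=(1.1, 1.5))  # no valid kappa in (0,1)


def test_spec_validation():
    with pytest.raises(ValueError):
        PassiveCellSpec(Rin=-1.0)
    with pytest.raises(ValueError):
        PassiveCellSpec(alpha=0.5)


def test_implied_area():
    # 40 pF at 0.9 uF/cm^2 -> 4444 um^2
    assert MSO_SPEC.area1_um2 == pytest.approx(4444.4, rel=1e-3)
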