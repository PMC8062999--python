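"""Fixed points, stability labels, folds, diagrams and phase planes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirswitch import (
    MmiParameters,
    ReducedState,
    bifurcation_diagram,
    classify_bistable,
    control_at_steady_state,
    fold_points,
    integrate_reduced,
    phase_plane,
    steady_states_at,
)
from mirswitch.steady_state import SADDLE, STABLE

REPRESENTATIVE = {
    "coop_mrna_deg": dict(a=(1.0, 10.0), b=(1.0, 1.0)),
    "coop_mirna_deg": dict(a=(1.0, 1.0), b=(1.0, 0.1)),
    "tdmd": dict(a=(1.0, 1.8), b=(1.8, 1.0)),
}


@pytest.mark.parametrize("kin", REPRESENTATIVE.values(), ids=REPRESENTATIVE.keys())
def test_representative_sets_have_two_nodes_and_a_saddle(kin):
    """Inside its bistable window each representative circuit has exactly
    three fixed points: two stable nodes and one saddle."""
    p = MmiParameters(n_sites=2, K_scaled=1e-5, **kin)
    rec = classify_bistable(p)
    assert rec.bistable
    mid = 0.5 * sum(rec.fold_controls)
    states = steady_states_at(p, mid)
    assert len(states) == 3
    labels = sorted(s.stability for s in states)
    assert labels.count(STABLE) == 2 and labels.count(SADDLE) == 1


def test_balanced_circuit_is_monostable_across_controls(balanced_two_site):
    for s_r in np.linspace(0.01, 4.0, 12):
        states = steady_states_at(balanced_two_site, s_r)
        assert len(states) == 1
        assert states[0].stable


def test_control_inversion_identity(fig4d_left):
    for r in (1e-6, 1e-4, 1e-2):
        c = float(control_at_steady_state(r, fig4d_left))
        states = steady_states_at(fig4d_left, c)
        assert any(s.full.r == pytest.approx(r, rel=1e-6) for s in states)


def test_control_curve_vanishes_at_zero_mirna(fig4d_left):
    assert float(control_at_steady_state(1e-12, fig4d_left)) < 1e-6


def test_bistable_curve_has_two_interior_extrema(fig4d_left):
    folds = fold_points(fig4d_left)
    assert len(folds) == 2
    # finite-difference check that d(control)/dr = 0 at each fold
    for _, rec in folds:
        r = rec.full.r
        h = 1e-6 * r
        slope = (
            float(control_at_steady_state(r + h, fig4d_left))
            - float(control_at_steady_state(r - h, fig4d_left))
        ) / (2 * h)
        scale = float(control_at_steady_state(r, fig4d_left)) / r
        assert abs(slope) < 1e-4 * scale


def test_leading_eigenvalue_vanishes_at_folds(fig4d_left):
    for _, rec in fold_points(fig4d_left):
        assert abs(rec.leading_eigenvalue_real_part) < 1e-3


@settings(max_examples=40, deadline=None)
@given(seed=st.integers(0, 10_000), n_sites=st.integers(1, 3), s_r=st.floats(0.05, 4.0))
def test_fixed_point_count_never_exceeds_sites_plus_one(seed, n_sites, s_r):
    rng = np.random.default_rng(seed)
    p = MmiParameters(
        n_sites=n_sites,
        a=tuple(rng.uniform(0.125, 16, n_sites)),
        b=tuple(rng.uniform(0.125, 16, n_sites)),
        K_scaled=1e-5,
    )
    assert len(steady_states_at(p, s_r)) <= n_sites + 1


def test_polynomial_roots_agree_with_ode_attractors():
    """Attractors reached by integrating the reduced dynamics from random
    starts coincide with stable roots of the steady-state polynomial."""
    rng = np.random.default_rng(7)
    for _ in range(15):
        p = MmiParameters(
            n_sites=2,
            a=tuple(rng.uniform(0.125, 16, 2)),
            b=tuple(rng.uniform(0.125, 16, 2)),
            K_scaled=1e-5,
        )
        s_r = rng.uniform(0.1, 2.0)
        stable = [s for s in steady_states_at(p, s_r) if s.stable]
        assert stable
        for _ in range(4):
            start = ReducedState(rng.uniform(0, 3), rng.uniform(0, 3))
            end = integrate_reduced(p, start, control=s_r, t_end=400.0)
            dists = [
                abs(end.R_T - s.reduced.R_T) + abs(end.r_T - s.reduced.r_T)
                for s in stable
            ]
            ref = 1.0 + end.R_T + end.r_T
            assert min(dists) < 1e-4 * ref


def test_bifurcation_diagram_bistable_interval(fig4d_left):
    diag = bifurcation_diagram(fig4d_left, control_range=(0.0, 1.0), resolution=300)
    assert diag.bistable
    lo, hi = diag.bistable_interval
    assert 0.15 < lo < hi < 0.45
    assert len(diag.folds) == 2
    # upper branch holds more free mRNA than the lower branch at the folds
    upper = diag.branches[0][-1][1].full.R
    lower = diag.branches[-1][0][1].full.R
    assert upper > lower


def test_bifurcation_diagram_empty_for_balanced(balanced_two_site):
    diag = bifurcation_diagram(balanced_two_site, control_range=(0.0, 4.0))
    assert not diag.bistable
    assert diag.folds == []


def test_bifurcation_rejects_bad_range(fig4d_left):
    with pytest.raises(ValueError):
        bifurcation_diagram(fig4d_left, control_range=(1.0, 1.0))


def test_phase_plane_structure_bistable(fig4d_left):
    rec = classify_bistable(fig4d_left)
    mid = 0.5 * sum(rec.fold_controls)
    pp = phase_plane(fig4d_left, control=mid)
    assert len(pp.steady_states) == 3
    assert pp.status == "ok"
    assert len(pp.separatrix) > 10
    # every steady state lies on both nullclines
    for s in pp.steady_states:
        pt = np.array([s.reduced.R_T, s.reduced.r_T])
        for curve in (pp.nullcline_R, pp.nullcline_r):
            d = np.min(np.linalg.norm(curve - pt, axis=1))
            assert d < 5e-2 * (1.0 + np.linalg.norm(pt))


def test_phase_plane_separatrix_separates_basins(fig4d_left):
    rec = classify_bistable(fig4d_left)
    mid = 0.5 * sum(rec.fold_controls)
    pp = phase_plane(fig4d_left, control=mid)
    stables = [s for s in pp.steady_states if s.stable]
    saddle = next(s for s in pp.steady_states if s.stability == SADDLE)
    # start on either side of the saddle along the unstable direction
    ends = []
    for sign in (+1, -1):
        start = ReducedState(
            max(saddle.reduced.R_T * (1 + sign * 0.05), 1e-9),
            max(saddle.reduced.r_T * (1 - sign * 0.05), 1e-9),
        )
        end = integrate_reduced(fig4d_left, start, control=mid, t_end=600.0)
        dists = [abs(end.R_T - s.reduced.R_T) + abs(end.r_T - s.reduced.r_T) for s in stables]
        ends.append(int(np.argmin(dists)))
    assert set(ends) == {0, 1}


def test_phase_plane_monostable_has_empty_separatrix(balanced_two_site):
    pp = phase_plane(balanced_two_site, control=1.0)
    assert len(pp.steady_states) == 1
    assert "no saddle" in pp.status
    assert pp.separatrix.shape[0] == 0
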