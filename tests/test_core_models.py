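"""Complex equilibria, reduced/full right-hand sides, competitor model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from mirswitch import (
    CompetitorParameters,
    FullState,
    MmiParameters,
    ReducedState,
    build_competitor_model,
    full_rhs,
    integrate_reduced,
    reduced_rhs,
    solve_complexes,
    steady_states_at,
)


def test_no_mirna_means_no_complexes():
    p = MmiParameters(n_sites=2, a=(1, 1), b=(1, 1))
    fs = solve_complexes(5.0, 0.0, p)
    assert fs.R == pytest.approx(5.0)
    assert fs.r == 0.0
    assert all(c == 0.0 for c in fs.C)


def test_weak_affinity_limit_leaves_species_free():
    p = MmiParameters(n_sites=2, a=(1, 1), b=(1, 1), K_scaled=1e6)
    fs = solve_complexes(1.0, 1.0, p)
    assert fs.R == pytest.approx(1.0, rel=1e-5)
    assert fs.r == pytest.approx(1.0, rel=1e-5)
    assert sum(fs.C) < 1e-5


def test_solve_complexes_matches_bracketing_oracle():
    """Independent oracle: solve the scalar conservation equation for free
    miRNA by exhaustive bisection with the binding algebra written out."""
    p = MmiParameters(
        n_sites=2, a=(1, 1), b=(1, 1), K_scaled=1e-5, binding_convention="plain"
    )
    R_T, r_T = 1.0, 1.0
    K = p.K_scaled

    def h(r):
        x = r / K
        phi0 = 1 + x + x**2
        psi0 = x + 2 * x**2
        return r + R_T * psi0 / phi0 - r_T

    r_oracle = bisect(h, 0.0, r_T, xtol=1e-16)
    x = r_oracle / K
    R_oracle = R_T / (1 + x + x**2)
    fs = solve_complexes(R_T, r_T, p)
    assert fs.r == pytest.approx(r_oracle, rel=1e-8, abs=1e-14)
    assert fs.R == pytest.approx(R_oracle, rel=1e-8)
    assert fs.C[0] == pytest.approx(R_oracle * x, rel=1e-8)
    assert fs.C[1] == pytest.approx(R_oracle * x**2, rel=1e-8)


def test_negative_totals_rejected():
    p = MmiParameters(n_sites=1, a=(1,), b=(1,))
    with pytest.raises(ValueError):
        solve_complexes(-1.0, 0.5, p)


@settings(max_examples=60, deadline=None)
@given(
    n_sites=st.integers(1, 3),
    log_RT=st.floats(-3, 2),
    log_rT=st.floats(-3, 2),
    log_K=st.floats(-6, 1),
    seed=st.integers(0, 10_000),
    convention=st.sampled_from(["plain", "statistical_factors"]),
)
def test_conservation_identities_hold(n_sites, log_RT, log_rT, log_K, seed, convention):
    rng = np.random.default_rng(seed)
    p = MmiParameters(
        n_sites=n_sites,
        a=tuple(rng.uniform(0.125, 16, n_sites)),
        b=tuple(rng.uniform(0.125, 16, n_sites)),
        K_scaled=10.0**log_K,
        binding_convention=convention,
    )
    R_T, r_T = 10.0**log_RT, 10.0**log_rT
    fs = solve_complexes(R_T, r_T, p)
    ref = 1.0 + R_T + r_T
    assert abs(fs.total_mrna - R_T) <= 1e-9 * ref
    assert abs(fs.total_mirna - r_T) <= 1e-8 * ref
    assert fs.R >= 0 and fs.r >= 0 and all(c >= 0 for c in fs.C)


def test_reduced_rhs_pure_synthesis_at_origin():
    p = MmiParameters(n_sites=2, a=(2, 3), b=(1, 0.5), s_r=0.7)
    d = reduced_rhs(ReducedState(0.0, 0.0), p)
    assert d[0] == pytest.approx(p.s_R)
    assert d[1] == pytest.approx(0.7)


def test_reduced_rhs_vanishes_at_fixed_point(fig4d_left):
    rec = steady_states_at(fig4d_left, 0.25)[0]
    d = reduced_rhs(rec.reduced, fig4d_left, control=0.25)
    assert abs(d[0]) < 1e-8 and abs(d[1]) < 1e-8


def test_balanced_kinetics_reduce_to_pure_sequestration():
    """With all multipliers 1 the totals obey plain synthesis-decay
    dynamics: complexation changes nothing at the total level."""
    p = MmiParameters(n_sites=2, a=(1, 1), b=(1, 1), s_r=0.8, K_scaled=1e-4)
    rng = np.random.default_rng(0)
    for _ in range(25):
        R_T, r_T = rng.uniform(0, 5, 2)
        d = reduced_rhs(ReducedState(R_T, r_T), p)
        assert d[0] == pytest.approx(p.s_R - p.k_R * R_T, abs=1e-8)
        assert d[1] == pytest.approx(p.s_r - p.k_r * r_T, abs=1e-7)


def test_full_rhs_at_origin_is_pure_synthesis():
    p = MmiParameters(n_sites=3, a=(1, 2, 3), b=(1, 1, 1), s_r=0.3)
    d = full_rhs(FullState(0.0, 0.0, (0.0, 0.0, 0.0)), p, kon=100.0)
    assert d[0] == pytest.approx(p.s_R)
    assert d[1] == pytest.approx(0.3)
    assert np.allclose(d[2:], 0.0)


def test_binding_conserves_totals():
    """With negligible synthesis and decay, binding/unbinding leaves both
    totals invariant along a trajectory of the full model."""
    p = MmiParameters(
        n_sites=2, a=(1, 1), b=(1, 1), s_R=1e-12, s_r=0.0, k_R=1e-12, k_r=1e-12,
        K_scaled=1e-2,
    )
    y0 = np.array([1.0, 1.5, 0.0, 0.0])

    def rhs(_t, y):
        return full_rhs(FullState(y[0], y[1], tuple(y[2:])), p, kon=50.0)

    sol = solve_ivp(rhs, (0, 20), y0, rtol=1e-10, atol=1e-12)
    yf = sol.y[:, -1]
    assert yf[0] + yf[2] + yf[3] == pytest.approx(1.0, abs=1e-6)
    assert yf[1] + yf[2] + 2 * yf[3] == pytest.approx(1.5, abs=1e-6)


@pytest.mark.parametrize("control", [0.22, 0.27])
def test_tqssa_agrees_with_full_model_at_fast_binding(fig4d_left, control):
    """Reduced-model fixed points are fixed points of the full model when
    binding is fast (criterion: within 1%)."""
    for rec in steady_states_at(fig4d_left, control):
        if not rec.stable:
            continue
        y0 = rec.full.as_array()

        def rhs(_t, y):
            return full_rhs(FullState(*np.maximum(y[:2], 0), tuple(np.maximum(y[2:], 0))),
                            fig4d_left.with_control(control), kon=1e7)

        sol = solve_ivp(rhs, (0, 50), y0, method="LSODA", rtol=1e-9, atol=1e-14)
        yf = sol.y[:, -1]
        RT0, rT0 = rec.reduced.R_T, rec.reduced.r_T
        RT1 = yf[0] + yf[2] + yf[3]
        rT1 = yf[1] + yf[2] + 2 * yf[3]
        assert RT1 == pytest.approx(RT0, rel=0.01)
        assert rT1 == pytest.approx(rT0, rel=0.01)


# -- competitor extension ---------------------------------------------------


def _null_competitor(p):
    return CompetitorParameters(n_sites2=1, a2_vec=(1.0,), s_R2=0.0)


def test_null_competitor_collapses_to_base(fig4d_left):
    model = build_competitor_model(fig4d_left, _null_competitor(fig4d_left))
    r = 1e-5
    from mirswitch import control_at_steady_state

    assert model.control_at_steady_state(r) == pytest.approx(
        float(control_at_steady_state(r, fig4d_left)), rel=1e-10
    )
    assert model.is_bistable()


def test_weak_competitor_preserves_bistability(fig4d_left):
    q = CompetitorParameters(n_sites2=1, a2_vec=(1.0,), s_R2=0.1, K2_scaled=1e-5)
    model = build_competitor_model(fig4d_left, q)
    assert model.is_bistable()


def test_strong_competitor_suppresses_free_mirna(fig4d_left):
    """Raising competitor synthesis monotonically drains the shared free
    miRNA pool at steady state."""
    frees = []
    for s_R2 in (0.0, 1.0, 100.0):
        q = CompetitorParameters(n_sites2=1, a2_vec=(1.0,), s_R2=s_R2, K2_scaled=1e-5)
        model = build_competitor_model(fig4d_left, q)

        def rhs(_t, y):
            return model.rhs(np.maximum(y, 0.0), control=1.0)

        sol = solve_ivp(rhs, (0, 300), [0.1, 0.1, 2.0], method="LSODA", rtol=1e-8)
        _, _, r = model.solve_free(*np.maximum(sol.y[:, -1], 0.0))
        frees.append(r)
    assert frees[0] > frees[1] > frees[2]
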