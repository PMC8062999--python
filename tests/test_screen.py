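"""Sampling, bistability classification, the analytic condition and the
critical degradation-ratio threshold."""

import numpy as np
import pytest

from mirswitch import (
    MmiParameters,
    ReducedState,
    analytic_condition,
    classify_bistable,
    critical_ratio,
    integrate_reduced,
    max_fixed_point_count,
    run_screen,
    sample_parameters,
    steady_states_at,
)


def test_sampling_bounds_and_determinism():
    a = sample_parameters(200, 0.125, 16.0, n_sites=2, seed=42)
    b = sample_parameters(200, 0.125, 16.0, n_sites=2, seed=42)
    assert a == b
    vals = np.array([[*p.a, *p.b] for p in a])
    assert vals.min() > 0.125 and vals.max() < 16.0
    assert sample_parameters(5, 0.125, 16.0, seed=1) != sample_parameters(5, 0.125, 16.0, seed=2)


def test_sampling_near_degenerate_bounds():
    (p,) = sample_parameters(1, 1.0 - 1e-9, 1.0, n_sites=2, seed=0)
    assert all(abs(v - 1.0) < 1e-6 for v in p.a + p.b)


def test_sampling_rejects_bad_bounds():
    with pytest.raises(ValueError):
        sample_parameters(10, 16.0, 0.125)
    with pytest.raises(ValueError):
        sample_parameters(0, 0.125, 16.0)


def test_classify_representative_and_balanced(fig4d_left, balanced_two_site):
    rec = classify_bistable(fig4d_left)
    assert rec.bistable and rec.bistable_width > 0
    rec0 = classify_bistable(balanced_two_site)
    assert not rec0.bistable and rec0.bistable_width == 0.0


def test_classification_agrees_with_attractor_census():
    """Brute-force oracle: count attractors reached by integrating the
    reduced dynamics from a grid of starts at several controls."""
    rng = np.random.default_rng(3)
    params = sample_parameters(8, 0.125, 16.0, n_sites=2, seed=3)
    for p in params:
        rec = classify_bistable(p)
        if rec.bistable:
            controls = np.linspace(*rec.fold_controls, 5)[1:-1]
        else:
            controls = np.geomspace(0.05, 3.0, 3)
        census_bistable = False
        for c in controls:
            ends = []
            for R0 in (0.01, 1.5, 3.0):
                for r0 in (0.01, 2.0):
                    end = integrate_reduced(
                        p, ReducedState(R0, r0), control=float(c), t_end=400.0
                    )
                    ends.append((round(np.log10(end.R_T + 1e-12), 2),))
            if len({e for e in ends}) >= 2:
                census_bistable = True
                break
        assert census_bistable == rec.bistable


def test_analytic_condition_examples():
    bistable = MmiParameters(n_sites=2, a=(1, 10), b=(1, 1))
    balanced = MmiParameters(n_sites=2, a=(1, 1), b=(1, 1))
    assert analytic_condition(bistable)
    assert not analytic_condition(balanced)
    with pytest.raises(ValueError):
        analytic_condition(MmiParameters(n_sites=1, a=(1,), b=(1,)))


def test_every_bistable_set_satisfies_analytic_condition():
    """The closed-form inequality is necessary for bistability (the
    converse need not hold)."""
    summary = run_screen(n_sites=2, n=400, seed=5)
    n_cond_only = 0
    for rec in summary.records:
        if rec.bistable:
            assert analytic_condition(rec.params)
        elif analytic_condition(rec.params):
            n_cond_only += 1
    assert summary.n_bistable > 0


@pytest.mark.parametrize(
    "a1,b1,expected",
    [(1.0, 1.0, 2.0), (2.0, 1.0, 4.0), (1.0, 2.0, 1.0)],
)
def test_critical_ratio_approaches_twice_a1_over_b1(a1, b1, expected):
    assert critical_ratio(a1, b1) == pytest.approx(expected, rel=0.01)


def test_screen_summary_bookkeeping():
    s = run_screen(n_sites=2, n=300, seed=9)
    assert s.n_total == 300 and s.n_failed == 0
    assert s.fraction_bistable == s.n_bistable / 300
    assert 0 < s.binomial_se < 0.05
    frame = s.to_frame()
    assert len(frame) == 300 and frame["bistable"].sum() == s.n_bistable


def test_one_site_circuit_never_bistable():
    params = sample_parameters(
        500, 0.01, 100.0, n_sites=1, seed=17, log_uniform=True, vary_all_rates=True
    )
    for p in params:
        assert not classify_bistable(p).bistable
    for p in params[:25]:
        assert max_fixed_point_count(p) == 1


def test_switch_metrics_majority_large_free_drop_small_total_change():
    summary = run_screen(n_sites=2, n=600, seed=21)
    bi = [r for r in summary.records if r.bistable]
    assert len(bi) > 100
    big_free = sum(r.free_mrna_drop_log10 > 3 for r in bi)
    small_total = sum(abs(r.total_mrna_change_log10) < 1 for r in bi)
    assert big_free > 0.5 * len(bi)
    assert small_total > 0.5 * len(bi)


def test_bistable_marginals_span_sampling_interval():
    """Bistability imposes no additional box constraint on individual
    multipliers: each bistable-conditional marginal spans (almost) the
    whole sampled interval."""
    summary = run_screen(n_sites=2, n=2000, seed=33)
    vals = np.array(
        [[*r.params.a, *r.params.b] for r in summary.records if r.bistable]
    )
    lo, hi = 0.125, 16.0
    for j in range(4):
        span = (vals[:, j].max() - vals[:, j].min()) / (hi - lo)
        assert span >= 0.9
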