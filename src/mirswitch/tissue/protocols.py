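"""In-silico experiments: knockouts, positional bifurcation, RA pulses.

The per-cell steady-state solver exploits the wiring of the boundary
models: the Hoxc8 side never depends on Hoxa5 protein (except in the
cross-repression variant, handled by a scalar composition scan), so all
fixed points factor into Hoxc8-side states times Hoxa5-side states given
the Hoxc8 protein level.  Titration arms are solved exactly through the
steady-state polynomial of the reduced pair model; purely
transcriptional/catalytic arms reduce to scalar fixed-point equations
solved by dense sign-change bracketing, with the composite loop gain
deciding stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ..parameters import MmiParameters
from ..steady_state import steady_states_at
from .metrics import (
    A5OFF_C8ON,
    A5ON_C8OFF,
    DOUBLE_OFF,
    DOUBLE_ON,
    FateThresholds,
)
from .models import CellModelSpec
from .morphogen import MorphogenConfig, MorphogenField, make_morphogen_field
from .simulate import simulate_single_cell

__all__ = [
    "knockout",
    "CellSteadyState",
    "cell_steady_states",
    "default_initial",
    "PositionalBifurcation",
    "positional_bifurcation",
    "RAPulseResult",
    "ra_pulse_experiment",
]

_TINY = 1e-12


def knockout(spec: CellModelSpec, mirna: str) -> CellModelSpec:
    """Zero the synthesis of the named miRNA in every cell."""
    return spec.knockout(mirna)


def default_initial(spec: CellModelSpec, pool_factor: float = 5.0) -> dict[str, float]:
    """Initial condition: naive cells with resting miRNA pools.

    mRNAs and proteins start at zero; each miRNA starts from a
    pre-differentiation pool, ``pool_factor`` times the free level its
    basal synthesis sustains.  A generous pool makes the
    miRNA-dominant (silenced) state the attractor of naive cells, so
    only a morphogen pulse can drive them onto the mRNA-high branch.
    """
    zero_levels = {s: 0.0 for s in spec.species}
    zero_levels.update(RA=0.0, FGF=0.0)
    init = dict(zero_levels)
    init.pop("RA"), init.pop("FGF")
    for s in spec.mirna_species:
        init[s] = pool_factor * float(spec.transcription[s].rate(zero_levels)) / spec.k_r
    return init


@dataclass(frozen=True)
class CellSteadyState:
    levels: dict  # totals, free forms and proteins
    stable: bool

    @property
    def Pa(self) -> float:
        return self.levels["Pa"]

    @property
    def Pc(self) -> float:
        return self.levels["Pc"]


def _arm_states(spec: CellModelSpec, pr, s_R: float, s_r: float):
    """(R_free, R_total, r_free, r_total, stable) of one titration arm."""
    if s_r <= _TINY:
        R = s_R / spec.k_R
        return [(R, R, 0.0, 0.0, True)]
    if s_R <= _TINY:
        return [(0.0, 0.0, s_r / spec.k_r, s_r / spec.k_r, True)]
    kin = MmiParameters(
        n_sites=len(pr.a),
        a=pr.a,
        b=pr.b,
        s_R=s_R,
        s_r=s_r,
        k_R=spec.k_R,
        k_r=spec.k_r,
        K_scaled=pr.K_scaled,
        binding_convention=pr.binding_convention,
    )
    out = []
    for rec in steady_states_at(kin, s_r):
        out.append(
            (rec.full.R, rec.reduced.R_T, rec.full.r, rec.reduced.r_T, rec.stable)
        )
    return out


def _scalar_fixed_points(f, hi: float, n_grid: int = 500):
    """Fixed points of a scalar map on [0, hi]; stability = |gain| < 1."""
    grid = np.linspace(0.0, hi, n_grid)
    vals = np.array([f(g) for g in grid]) - grid
    out = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
            p = brentq(lambda z: f(z) - z, grid[i], grid[i + 1], xtol=1e-12)
            h = 1e-6 * (1.0 + p)
            gain = (f(p + h) - f(max(p - h, 0.0))) / (p + h - max(p - h, 0.0))
            out.append((p, abs(gain) < 1.0))
    if not out:  # map entirely above/below: take the boundary attractor
        p = hi if vals[-1] > 0 else 0.0
        out.append((p, True))
    return out


def _side_states(spec: CellModelSpec, mrna: str, protein: str, levels: dict):
    """Steady states of one mRNA/miRNA/protein arm given the other protein."""
    unit = spec.transcription[mrna]
    pr = spec.pair_for(mrna)
    cat = next((c for c in spec.catalytic if c.mrna == mrna), None)
    mirna = (
        pr.mirna
        if pr is not None
        else (cat.mirna if cat is not None else None)
    )
    mi_unit = spec.transcription.get(mirna) if mirna else None
    mi_self = mi_unit is not None and any(e.regulator == protein for e in mi_unit.edges)

    def protein_of(R_free, m_level, lv):
        syn = spec.k_tl * R_free
        if cat is not None:
            syn = syn / (1.0 + m_level / cat.theta_tl)
        return syn / spec.k_p

    def states_given_protein(P):
        lv = dict(levels)
        lv[protein] = P
        s_R = float(unit.rate(lv))
        if pr is not None:
            s_r = float(mi_unit.rate(lv))
            return [
                dict(
                    **{mrna: RT, mirna: rT, protein: protein_of(R, 0.0, lv)},
                    **{f"{mrna}_free": R, f"{mirna}_free": r},
                    stable=st,
                )
                for R, RT, r, rT, st in _arm_states(spec, pr, s_R, s_r)
            ]
        if cat is not None:
            m = float(mi_unit.rate(lv)) / spec.k_r
            R = s_R / (spec.k_R + cat.k_cat * m)
            return [
                dict(
                    **{mrna: R, mirna: m, protein: protein_of(R, m, lv)},
                    **{f"{mrna}_free": R, f"{mirna}_free": m},
                    stable=True,
                )
            ]
        R = s_R / spec.k_R
        return [dict(**{mrna: R, protein: protein_of(R, 0.0, lv), f"{mrna}_free": R}, stable=True)]

    if not mi_self and not any(e.regulator == protein for e in unit.edges):
        return states_given_protein(0.0)

    # the arm feeds back on itself through its own protein: scalar scan
    p_max = 2.0 * spec.k_tl * (unit.basal + unit.induced) / (spec.k_R * spec.k_p) + 1.0

    def f(P):
        cands = states_given_protein(P)
        stable = [c for c in cands if c["stable"]] or cands
        # branch continuation: follow the candidate closest to the probe
        best = min(stable, key=lambda c: abs(c[protein] - P))
        return best[protein]

    out = []
    for P, st in _scalar_fixed_points(f, p_max):
        cands = states_given_protein(P)
        best = min(cands, key=lambda c: abs(c[protein] - P))
        best = dict(best)
        best["stable"] = bool(best["stable"] and st)
        out.append(best)
    return out


def cell_steady_states(spec: CellModelSpec, ra: float, fgf: float) -> list[CellSteadyState]:
    """All fixed points of one cell at frozen signal levels."""
    base_levels = {s: 0.0 for s in spec.species}
    base_levels.update(RA=float(ra), FGF=float(fgf))

    c8_coupled = any(
        e.regulator == "Pa" for e in spec.transcription["Rc"].edges
    )
    out = []
    if not c8_coupled:
        for c8 in _side_states(spec, "Rc", "Pc", base_levels):
            lv = dict(base_levels)
            lv.update({k: v for k, v in c8.items() if k != "stable"})
            for a5 in _side_states(spec, "Ra", "Pa", lv):
                levels = {k: v for k, v in {**c8, **a5}.items() if k != "stable"}
                out.append(
                    CellSteadyState(levels=levels, stable=bool(c8["stable"] and a5["stable"]))
                )
        return out

    # mutual transcriptional coupling (T_CR): scan the Pa -> Pa composition
    unit_a = spec.transcription["Ra"]
    p_max = 2.0 * spec.k_tl * (unit_a.basal + unit_a.induced) / (spec.k_R * spec.k_p) + 1.0

    def c8_of(Pa):
        lv = dict(base_levels)
        lv["Pa"] = Pa
        return _side_states(spec, "Rc", "Pc", lv)[0]

    def f(Pa):
        lv = dict(base_levels)
        lv.update({k: v for k, v in c8_of(Pa).items() if k != "stable"})
        return _side_states(spec, "Ra", "Pa", lv)[0]["Pa"]

    for Pa, st in _scalar_fixed_points(f, p_max):
        c8 = c8_of(Pa)
        lv = dict(base_levels)
        lv.update({k: v for k, v in c8.items() if k != "stable"})
        a5 = _side_states(spec, "Ra", "Pa", lv)[0]
        levels = {k: v for k, v in {**c8, **a5}.items() if k != "stable"}
        out.append(CellSteadyState(levels=levels, stable=st))
    return out


@dataclass
class PositionalBifurcation:
    """Per-position fixed points of the single-cell model with the
    morphogens frozen at their final (receded) profiles."""

    positions: np.ndarray
    states: list[list[CellSteadyState]]
    theta_a: float
    theta_c: float

    def labels_at(self, i: int, stable_only: bool = True) -> set[str]:
        out = set()
        for st in self.states[i]:
            if stable_only and not st.stable:
                continue
            on_a, on_c = st.Pa >= self.theta_a, st.Pc >= self.theta_c
            out.add(
                DOUBLE_ON
                if on_a and on_c
                else A5ON_C8OFF
                if on_a
                else A5OFF_C8ON
                if on_c
                else DOUBLE_OFF
            )
        return out

    def n_stable(self, i: int) -> int:
        return sum(st.stable for st in self.states[i])

    def tristable_window(self) -> np.ndarray:
        """Positions where the rostral, caudal and naive states co-exist."""
        want = {A5ON_C8OFF, A5OFF_C8ON, DOUBLE_OFF}
        return np.array(
            [want <= self.labels_at(i) for i in range(len(self.positions))]
        )


def positional_bifurcation(
    spec: CellModelSpec,
    field: MorphogenField | None = None,
    positions=None,
    thresholds: FateThresholds | None = None,
) -> PositionalBifurcation:
    field = field or make_morphogen_field(MorphogenConfig(), seed=0)
    ra, fgf = field.final_backbone()
    if positions is None:
        positions = np.arange(field.cfg.n_positions)
    positions = np.asarray(positions)
    states = [cell_steady_states(spec, ra[i], fgf[i]) for i in positions]
    th = thresholds or FateThresholds()
    pa_max = max((st.Pa for col in states for st in col if st.stable), default=1.0)
    pc_max = max((st.Pc for col in states for st in col if st.stable), default=1.0)
    theta_a = th.theta_a if th.theta_a is not None else th.on_fraction * pa_max
    theta_c = th.theta_c if th.theta_c is not None else th.on_fraction * pc_max
    return PositionalBifurcation(
        positions=positions,
        states=states,
        theta_a=theta_a,
        theta_c=theta_c,
    )


@dataclass
class RAPulseResult:
    pa_pulsed: float
    pa_unpulsed: float
    pa_high_phase: float
    persistent: bool
    on_threshold: float
    above_threshold: bool
    bistable_window: tuple[float, float] | None
    times: np.ndarray
    pa_trace: np.ndarray


def ra_pulse_experiment(
    spec: CellModelSpec,
    ra_high: float = 1.0,
    ra_low: float = 0.005,
    t_switch: float = 60.0,
    mir27_active: bool = True,
    t_end: float = 160.0,
    persistence_fold: float = 3.0,
) -> RAPulseResult:
    """Transient-high RA exposure of a single cell, with the miR-27 arm
    intact or silenced.

    Memory is scored two ways: *persistence* compares the pulsed cell's
    final Hoxa5 protein against a never-pulsed control held at
    ``ra_low`` throughout; the *on-threshold* is the geometric midpoint
    between the two stable branches at ``ra_low`` when the RA response
    is bistable, and a tenth of the maximal attainable level otherwise
    (a monostable response has no branch structure to separate).
    """
    if not ra_high > ra_low >= 0:
        raise ValueError("need ra_high > ra_low >= 0")
    model = spec if mir27_active else spec.knockout("m27")
    init = default_initial(model)

    def ra_pulse(t):
        return ra_high if t < t_switch else ra_low

    times, traj = simulate_single_cell(
        model, ra_pulse, lambda t: 0.0, t_end=t_end, initial=init
    )
    pa = model.free_species({k: np.atleast_1d(v) for k, v in traj.items()})
    pa_trace = traj["Pa"]
    pa_pulsed = float(pa_trace[-1])
    pa_high_phase = float(pa_trace[np.searchsorted(times, t_switch) - 1])

    _, traj0 = simulate_single_cell(
        model, lambda t: ra_low, lambda t: 0.0, t_end=t_end, initial=init
    )
    pa_unpulsed = float(traj0["Pa"][-1])

    # single-cell bifurcation with RA as the control parameter; the grid
    # is log-dense at low RA where the fold structure lives
    ra_grid = np.unique(
        np.concatenate(
            [
                [0.0, ra_low],
                np.geomspace(1e-4, max(ra_high * 1.2, 1e-3), 80),
                np.linspace(0.0, max(ra_high * 1.2, 1e-3), 20),
            ]
        )
    )
    window = None
    lo = hi = None
    branch_at_low: list[float] = []
    for ra in ra_grid:
        stables = [st.Pa for st in cell_steady_states(model, ra, 0.0) if st.stable]
        if len(stables) >= 2:
            lo = ra if lo is None else lo
            hi = ra
    if lo is not None and hi is not None and hi > lo:
        window = (float(lo), float(hi))
    branch_at_low = sorted(
        st.Pa for st in cell_steady_states(model, ra_low, 0.0) if st.stable
    )
    if len(branch_at_low) >= 2 and branch_at_low[0] > 0:
        threshold = float(np.sqrt(branch_at_low[0] * branch_at_low[-1]))
    else:
        high_state = max(
            (st.Pa for st in cell_steady_states(model, ra_high, 0.0) if st.stable),
            default=pa_high_phase,
        )
        threshold = 0.1 * float(high_state)

    persistent = pa_pulsed > persistence_fold * max(pa_unpulsed, 1e-12)
    return RAPulseResult(
        pa_pulsed=pa_pulsed,
        pa_unpulsed=pa_unpulsed,
        pa_high_phase=pa_high_phase,
        persistent=persistent,
        on_threshold=threshold,
        above_threshold=pa_pulsed >= threshold,
        bistable_window=window,
        times=times,
        pa_trace=pa_trace,
    )
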