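"""Steady states, stability and bifurcation structure of the reduced model.

At a fixed point the mRNA balance pins free mRNA to
``R = (s_R/k_R) / phi_a(x)`` with ``x = r/K``, so the miRNA balance turns
into a single closed-form curve

    s_r(r) = k_r * ( r + (s_R/k_R) * psi_b(x) / phi_a(x) ),

the miRNA synthesis rate at which free-miRNA level ``r`` is stationary.
Every question about fixed points becomes a question about this rational
curve: fixed points at a given control are polynomial roots, saddle-node
(fold) points are its interior extrema, and bistability is its
non-monotonicity.  Branches are therefore traced by sweeping ``r`` (the
natural parameter along the S-curve) rather than the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P

from .core import reduced_rhs, solve_complexes
from .parameters import FullState, MmiParameters, ReducedState

__all__ = [
    "SteadyStateRecord",
    "BifurcationDiagram",
    "PhasePlane",
    "sr_curve_polys",
    "control_at_steady_state",
    "steady_states_at",
    "fold_points",
    "bifurcation_diagram",
    "phase_plane",
    "reduced_jacobian",
]

#: absolute clustering tolerance (relative to magnitude) for degenerate roots
FOLD_CLUSTER_TOL = 1e-8

STABLE = "stable_node_or_focus"
SADDLE = "saddle"
UNSTABLE = "unstable"


@dataclass(frozen=True)
class SteadyStateRecord:
    reduced: ReducedState
    full: FullState
    stability: str
    leading_eigenvalue_real_part: float
    control_value: float
    degenerate: bool = False

    @property
    def stable(self) -> bool:
        return self.stability == STABLE


@dataclass
class BifurcationDiagram:
    """Branches of steady states versus a control parameter."""

    control_name: str
    branches: list[list[tuple[float, SteadyStateRecord]]]
    folds: list[tuple[float, SteadyStateRecord]]
    bistable_interval: tuple[float, float] | None

    @property
    def bistable(self) -> bool:
        return self.bistable_interval is not None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, branch in enumerate(self.branches):
            for control, rec in branch:
                rows.append(
                    dict(
                        branch=bi,
                        control=control,
                        R_T=rec.reduced.R_T,
                        r_T=rec.reduced.r_T,
                        R=rec.full.R,
                        r=rec.full.r,
                        stability=rec.stability,
                    )
                )
        return pd.DataFrame(rows)


@dataclass
class PhasePlane:
    nullcline_R: np.ndarray  # (m, 2) points (R_T, r_T) where dR_T/dt = 0
    nullcline_r: np.ndarray  # (m, 2) points where dr_T/dt = 0
    steady_states: list[SteadyStateRecord]
    vector_field: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    separatrix: np.ndarray  # (m, 2) polyline, empty when no saddle
    status: str = "ok"


# ---------------------------------------------------------------------------
# the steady-state curve
# ---------------------------------------------------------------------------


def sr_curve_polys(p: MmiParameters):
    """Numerator and denominator of s_r(r) as polynomials in r (ascending)."""
    scale = p.K_scaled ** -np.arange(p.n_sites + 1)
    pa = p.poly_mrna_decay() * scale
    pb = p.poly_mirna_decay() * scale
    num = P.polyadd(P.polymul([0.0, 1.0], pa), (p.s_R / p.k_R) * pb)
    return p.k_r * num, pa


def control_at_steady_state(r: float, p: MmiParameters) -> float:
    """The unique s_r for which ``r`` is a steady-state free-miRNA level."""
    num, den = sr_curve_polys(p)
    r = np.asarray(r, dtype=float)
    return P.polyval(r, num) / P.polyval(r, den)


def _real_positive_roots(coeffs) -> np.ndarray:
    coeffs = np.asarray(coeffs, dtype=float)
    nz = np.nonzero(np.abs(coeffs) > 0)[0]
    if len(nz) == 0:
        return np.array([])
    coeffs = coeffs[: nz[-1] + 1]
    if len(coeffs) < 2:
        return np.array([])
    roots = P.polyroots(coeffs)
    roots = roots[np.abs(roots.imag) < 1e-8 * (1.0 + np.abs(roots))].real
    return np.sort(roots[roots > 0])


def _cluster_roots(roots: np.ndarray):
    """Collapse near-multiple roots; returns (values, multiplicity)."""
    if len(roots) == 0:
        return [], []
    vals, mult = [roots[0]], [1]
    for v in roots[1:]:
        if abs(v - vals[-1]) <= FOLD_CLUSTER_TOL * (1.0 + abs(v)):
            mult[-1] += 1
            vals[-1] = 0.5 * (vals[-1] + v)
        else:
            vals.append(v)
            mult.append(1)
    return vals, mult


def reduced_jacobian(p: MmiParameters, full: FullState) -> np.ndarray:
    """Jacobian of the reduced 2-variable system at a species-resolved state.

    Obtained by the chain rule through the binding algebra: with
    ``T = (R_T, r_T)`` a smooth function of ``(R, r)``, the Jacobian in
    total coordinates is ``N M^{-1}`` where ``N`` and ``M`` differentiate
    the rates and the totals with respect to ``(R, r)``.
    """
    R, r = full.R, full.r
    K = p.K_scaled
    x = r / K

    def val_and_deriv(c):
        return P.polyval(x, c), P.polyval(x, P.polyder(c)) / K

    phi0, dphi0 = val_and_deriv(p.poly_occupancy())
    psi0, dpsi0 = val_and_deriv(p.poly_bound())
    phia, dphia = val_and_deriv(p.poly_mrna_decay())
    psib, dpsib = val_and_deriv(p.poly_mirna_decay())

    M = np.array([[phi0, R * dphi0], [psi0, 1.0 + R * dpsi0]])
    N = np.array(
        [
            [-p.k_R * phia, -p.k_R * R * dphia],
            [-p.k_r * psib, -p.k_r * (1.0 + R * dpsib)],
        ]
    )
    return N @ np.linalg.inv(M)


def _label_stability(J: np.ndarray):
    eigs = np.linalg.eigvals(J)
    lead = float(np.max(eigs.real))
    det = float(np.linalg.det(J))
    if det < 0:
        return SADDLE, lead
    return (STABLE, lead) if lead < 0 else (UNSTABLE, lead)


def _record_at_r(p: MmiParameters, r: float, control: float, degenerate=False):
    x = r / p.K_scaled
    R = (p.s_R / p.k_R) / P.polyval(x, p.poly_mrna_decay())
    c = p.site_multiplicity
    C = tuple(c[i] * R * x ** (i + 1) for i in range(p.n_sites))
    full = FullState(R=R, r=r, C=C)
    reduced = ReducedState(full.total_mrna, full.total_mirna)
    stability, lead = _label_stability(reduced_jacobian(p, full))
    return SteadyStateRecord(
        reduced=reduced,
        full=full,
        stability=stability,
        leading_eigenvalue_real_part=lead,
        control_value=control,
        degenerate=degenerate,
    )


def steady_states_at(p: MmiParameters, control: float) -> list[SteadyStateRecord]:
    """All positive fixed points of the reduced model at miRNA synthesis
    rate ``control``, labeled by Jacobian stability.

    Found by exhaustive real-root extraction of the steady-state
    polynomial ``num(r) - control * den(r)`` (degree ``n_sites + 1``);
    near-multiple roots (at a fold) are clustered and flagged degenerate.
    """
    if control < 0:
        raise ValueError("control (miRNA synthesis rate) must be nonnegative")
    num, den = sr_curve_polys(p)
    roots = _real_positive_roots(P.polysub(num, control * den))
    vals, mult = _cluster_roots(roots)
    return [_record_at_r(p, v, control, degenerate=m > 1) for v, m in zip(vals, mult)]


def fold_points(p: MmiParameters) -> list[tuple[float, SteadyStateRecord]]:
    """Saddle-node points: interior extrema of the steady-state curve."""
    num, den = sr_curve_polys(p)
    dpoly = P.polysub(P.polymul(P.polyder(num), den), P.polymul(num, P.polyder(den)))
    out = []
    for r in _real_positive_roots(dpoly):
        control = float(P.polyval(r, num) / P.polyval(r, den))
        out.append((control, _record_at_r(p, float(r), control, degenerate=True)))
    return out


def bifurcation_diagram(
    p: MmiParameters,
    control_range: tuple[float, float] = (0.0, 4.0),
    resolution: int = 400,
) -> BifurcationDiagram:
    """One-parameter bifurcation diagram in the miRNA synthesis rate.

    Branches are swept in ``r`` (the curve's natural parameter), so folds
    are resolved exactly as the curve's extrema; branch k collects states
    with k folds below their free-miRNA level.
    """
    lo, hi = control_range
    if not hi > lo or lo < 0:
        raise ValueError(f"invalid control range {control_range}")
    num, den = sr_curve_polys(p)
    folds = [(c, rec) for c, rec in fold_points(p) if lo <= c <= hi]
    fold_rs = sorted(rec.full.r for _, rec in folds)

    # r-range covering every branch visible in the control window
    endpoints = _real_positive_roots(P.polysub(num, hi * den))
    r_max = float(endpoints.max()) if len(endpoints) else 1.0
    tiny = _real_positive_roots(P.polysub(num, max(lo, hi * 1e-9) * den))
    r_min = float(tiny.min()) if len(tiny) else r_max * 1e-12
    grid = np.geomspace(max(r_min, 1e-300), r_max, resolution)
    grid = np.sort(np.concatenate([grid, np.asarray(fold_rs) * (1 + 1e-9)]))

    branches: dict[int, list] = {}
    for r in grid:
        control = float(P.polyval(r, num) / P.polyval(r, den))
        if not lo <= control <= hi:
            continue
        k = int(np.searchsorted(fold_rs, r))
        branches.setdefault(k, []).append((control, _record_at_r(p, float(r), control)))

    interval = None
    if len(folds) >= 2:
        vals = [c for c, _ in folds]
        blo, bhi = max(min(vals), lo), min(max(vals), hi)
        if bhi > blo:
            interval = (blo, bhi)
    return BifurcationDiagram(
        control_name="s_r",
        branches=[branches[k] for k in sorted(branches)],
        folds=folds,
        bistable_interval=interval,
    )


# ---------------------------------------------------------------------------
# phase plane
# ---------------------------------------------------------------------------


def _nullcline_points(p: MmiParameters, control: float, r_grid: np.ndarray, which: str):
    pts = []
    for r in r_grid:
        x = r / p.K_scaled
        if which == "R":
            R = (p.s_R / p.k_R) / P.polyval(x, p.poly_mrna_decay())
        else:
            psib = P.polyval(x, p.poly_mirna_decay())
            if psib <= 0:
                continue
            R = (control / p.k_r - r) / psib
            if R < 0:
                continue
        phi0 = P.polyval(x, p.poly_occupancy())
        psi0 = P.polyval(x, p.poly_bound())
        pts.append((R * phi0, r + R * psi0))
    return np.asarray(pts) if pts else np.empty((0, 2))


def phase_plane(
    p: MmiParameters,
    control: float | None = None,
    n_grid: int = 15,
    n_curve: int = 400,
    separatrix_span: float = 400.0,
) -> PhasePlane:
    """Nullclines, sampled vector field and separatrix in (R_T, r_T).

    The nullclines are computed in closed form as curves parameterized by
    free miRNA; the separatrix is the saddle's stable manifold, obtained
    by integrating the reduced flow backward in time from the saddle
    along its stable eigendirections.
    """
    from scipy.integrate import solve_ivp

    control = p.s_r if control is None else control
    states = steady_states_at(p, control)
    r_vals = [s.full.r for s in states] or [p.K_scaled]
    r_grid = np.geomspace(min(r_vals) * 1e-3 + 1e-300, max(r_vals) * 1e3, n_curve)
    ncl_R = _nullcline_points(p, control, r_grid, "R")
    ncl_r = _nullcline_points(p, control, r_grid, "r")

    R_T_max = 2.0 * max([s.reduced.R_T for s in states] + [p.s_R / p.k_R])
    r_T_max = 2.0 * max([s.reduced.r_T for s in states] + [control / p.k_r + 1.0])
    RT, rT = np.meshgrid(
        np.linspace(R_T_max * 1e-3, R_T_max, n_grid),
        np.linspace(r_T_max * 1e-3, r_T_max, n_grid),
    )
    U = np.zeros_like(RT)
    V = np.zeros_like(rT)
    for idx in np.ndindex(RT.shape):
        U[idx], V[idx] = reduced_rhs(ReducedState(RT[idx], rT[idx]), p, control)

    saddles = [s for s in states if s.stability == SADDLE]
    status = "ok"
    sep = np.empty((0, 2))
    if not saddles:
        status = "no saddle: separatrix empty"
    else:
        sad = saddles[0]
        J = reduced_jacobian(p, sad.full)
        eigval, eigvec = np.linalg.eig(J)
        stable_dirs = [eigvec[:, i].real for i in range(2) if eigval[i].real < 0]
        y0 = np.array([sad.reduced.R_T, sad.reduced.r_T])

        def back_rhs(_t, y):
            d = reduced_rhs(ReducedState(max(y[0], 0.0), max(y[1], 0.0)), p, control)
            return [-d[0], -d[1]]

        def out_of_box(_t, y):
            return min(3.0 * R_T_max - y[0], 3.0 * r_T_max - y[1], y[0] + 1e-9, y[1] + 1e-9)

        out_of_box.terminal = True

        pieces = []
        eps = 1e-6 * (1.0 + np.linalg.norm(y0))
        for v in stable_dirs:
            for sign in (+1.0, -1.0):
                sol = solve_ivp(
                    back_rhs,
                    (0.0, separatrix_span),
                    y0 + sign * eps * v / np.linalg.norm(v),
                    method="LSODA",
                    rtol=1e-8,
                    atol=1e-12,
                    dense_output=False,
                    events=out_of_box,
                    max_step=separatrix_span / 50,
                )
                ys = sol.y.T
                keep = (
                    (ys[:, 0] >= 0)
                    & (ys[:, 1] >= 0)
                    & (ys[:, 0] <= 3 * R_T_max)
                    & (ys[:, 1] <= 3 * r_T_max)
                )
                pieces.append(ys[keep])
        if pieces:
            sep = np.vstack([pieces[1][::-1], pieces[0]]) if len(pieces) >= 2 else pieces[0]

    return PhasePlane(
        nullcline_R=ncl_R,
        nullcline_r=ncl_r,
        steady_states=states,
        vector_field=(RT, rT, U, V),
        separatrix=sep,
        status=status,
    )
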