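"""Right-hand sides and complex equilibria of the titration circuit.

The full model tracks every species (free mRNA ``R``, free miRNA ``r``,
complexes ``C_1..C_n``) under mass action.  Because binding and unbinding
are much faster than synthesis and decay, the analysis object is the
reduced model obtained under the total quasi-steady-state assumption
(tQSSA): the slow variables are the totals ``R_T = R + sum C_i`` and
``r_T = r + sum i*C_i``, and the fast binding equilibrium
``C_i = c_i R (r/K)^i`` is imposed algebraically at every instant.

Degradation of a complex is an elementary step that removes one partner
and releases the survivor intact (multiple turnover): mRNA decay in
``C_i`` (rate ``a_i k_R``) frees the i bound miRNAs; decay of one bound
miRNA (total rate ``lambda_i b_i k_r``) leaves ``C_{i-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.optimize import brentq

from .parameters import CompetitorParameters, FullState, MmiParameters, ReducedState

__all__ = [
    "solve_complexes",
    "reduced_rhs",
    "full_rhs",
    "integrate_reduced",
    "CompetitorModel",
    "build_competitor_model",
]

#: relative residual allowed on the two conservation identities
RESIDUAL_TOL = 1e-12
#: relative tolerance of the inner root solves
ROOT_TOL = 1e-9


class ComplexSolveError(RuntimeError):
    """Inner equilibrium solve failed to converge."""


def _binding_fractions(p: MmiParameters, r):
    """Return (phi0, psi0) evaluated at the occupancy variable x = r/K."""
    x = np.asarray(r, dtype=float) / p.K_scaled
    return P.polyval(x, p.poly_occupancy()), P.polyval(x, p.poly_bound())


def solve_complexes(R_T: float, r_T: float, p: MmiParameters) -> FullState:
    """Solve the fast binding equilibrium for given totals.

    Finds the unique nonnegative ``(R, r, C_1..C_n)`` with
    ``C_i = c_i R (r/K)^i`` satisfying ``R + sum C_i = R_T`` and
    ``r + sum i C_i = r_T``.

    The problem reduces to one equation in free miRNA ``r``:
    ``h(r) = r + R_T psi0(r/K)/phi0(r/K) - r_T = 0`` with ``h`` strictly
    increasing on ``[0, r_T]``, solved as a polynomial with a bracketed
    bisection fallback.

    Raises
    ------
    ValueError
        If a total is negative.
    ComplexSolveError
        If neither the polynomial path nor bisection converges.
    """
    if R_T < 0 or r_T < 0:
        raise ValueError(f"totals must be nonnegative, got R_T={R_T}, r_T={r_T}")
    if r_T == 0.0 or R_T == 0.0:
        return _finish(R_T, r_T, float(r_T), p)

    # (r - r_T) * phi0(r/K) + R_T * psi0(r/K) = 0, as a polynomial in r
    K = p.K_scaled
    scale = K ** -np.arange(p.n_sites + 1)
    phi0_r = p.poly_occupancy() * scale
    psi0_r = p.poly_bound() * scale
    coeffs = P.polyadd(P.polymul([-r_T, 1.0], phi0_r), R_T * psi0_r)

    r = _positive_root_in(coeffs, 0.0, r_T)
    if r is None or not _residual_ok(R_T, r_T, r, p):
        r = _bisect_root(R_T, r_T, p)
    return _finish(R_T, r_T, r, p)


def _positive_root_in(coeffs, lo, hi):
    try:
        roots = P.polyroots(coeffs)
    except Exception:
        return None
    roots = roots[np.abs(roots.imag) < 1e-9 * (1.0 + np.abs(roots))].real
    roots = roots[(roots >= lo - 1e-12 * (1 + hi)) & (roots <= hi * (1 + 1e-12))]
    if len(roots) == 0:
        return None
    return float(np.clip(roots.min(), lo, hi))


def _bisect_root(R_T, r_T, p):
    def h(r):
        phi0, psi0 = _binding_fractions(p, r)
        return r + R_T * psi0 / phi0 - r_T

    try:
        return brentq(h, 0.0, r_T, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    except Exception as exc:  # pragma: no cover - defensive
        raise ComplexSolveError(
            f"binding equilibrium failed for R_T={R_T}, r_T={r_T}, p={p}"
        ) from exc


def _residual_ok(R_T, r_T, r, p):
    phi0, psi0 = _binding_fractions(p, r)
    R = R_T / phi0
    res_R = abs(R * phi0 - R_T)
    res_r = abs(r + R * psi0 - r_T)
    ref = 1.0 + abs(R_T) + abs(r_T)
    return res_R <= RESIDUAL_TOL * ref and res_r <= max(RESIDUAL_TOL * ref, 1e-10 * ref)


def _finish(R_T, r_T, r, p) -> FullState:
    phi0, _ = _binding_fractions(p, r)
    R = R_T / phi0 if phi0 > 0 else 0.0
    x = r / p.K_scaled
    c = p.site_multiplicity
    C = tuple(max(c[i] * R * x ** (i + 1), 0.0) for i in range(p.n_sites))
    return FullState(R=max(R, 0.0), r=max(r, 0.0), C=C)


def reduced_rhs(state: ReducedState, p: MmiParameters, control: float | None = None):
    """Time derivatives (dR_T/dt, dr_T/dt) of the reduced model.

    ``dR_T/dt = s_R - k_R (R + sum a_i C_i)`` and
    ``dr_T/dt = s_r - k_r (r + sum lambda_i b_i C_i)`` with the free/bound
    split taken from :func:`solve_complexes`.  ``control`` overrides the
    miRNA synthesis rate ``s_r``.
    """
    s_r = p.s_r if control is None else control
    full = solve_complexes(state.R_T, state.r_T, p)
    x = full.r / p.K_scaled
    dR_T = p.s_R - p.k_R * full.R * P.polyval(x, p.poly_mrna_decay())
    dr_T = s_r - p.k_r * (full.r + full.R * P.polyval(x, p.poly_mirna_decay()))
    return dR_T, dr_T


def full_rhs(state: FullState, p: MmiParameters, kon: float):
    """Mass-action derivatives of the unreduced model.

    Stepwise binding uses ``kon_i = (n-i+1) kon`` and ``koff_i = i K kon``
    under the statistical-factors convention (``kon_i = kon``,
    ``koff_i = K kon`` under ``plain``), which makes the fast-binding
    equilibrium consistent with :func:`solve_complexes`.

    Returns an array ``(dR, dr, dC_1..dC_n)``.
    """
    if kon <= 0:
        raise ValueError("kon must be positive")
    n = p.n_sites
    K = p.K_scaled
    stat = p.binding_convention == "statistical_factors"
    lam = p.mirna_loss_weight
    R, r, C = state.R, state.r, state.C
    occ = (R,) + C  # occ[i] = complex with i bound miRNAs (occ[0] = free mRNA)

    d = np.zeros(2 + n)
    d[0] += p.s_R - p.k_R * R
    d[1] += p.s_r - p.k_r * r
    for i in range(1, n + 1):  # binding step occ[i-1] + r <-> occ[i]
        kon_i = kon * (n - i + 1) if stat else kon
        koff_i = kon * K * i if stat else kon * K
        flux = kon_i * occ[i - 1] * r - koff_i * occ[i]
        d[1] -= flux
        d[1 + i] += flux
        if i == 1:
            d[0] -= flux
        else:
            d[i] -= flux
    for i in range(1, n + 1):
        Ci = C[i - 1]
        # mRNA degraded inside C_i: complex lost, i miRNAs recycled
        rate_m = p.a[i - 1] * p.k_R * Ci
        d[1 + i] -= rate_m
        d[1] += i * rate_m
        # one bound miRNA degraded: C_i -> C_{i-1}
        rate_r = lam[i - 1] * p.b[i - 1] * p.k_r * Ci
        d[1 + i] -= rate_r
        if i == 1:
            d[0] += rate_r
        else:
            d[i] += rate_r
    return d


def integrate_reduced(
    p: MmiParameters,
    state0: ReducedState,
    control: float | None = None,
    t_end: float = 200.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ReducedState:
    """Integrate the reduced model to (near) steady state."""
    from scipy.integrate import solve_ivp

    def rhs(_t, y):
        return reduced_rhs(ReducedState(max(y[0], 0.0), max(y[1], 0.0)), p, control)

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [state0.R_T, state0.r_T],
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    return ReducedState(max(sol.y[0, -1], 0.0), max(sol.y[1, -1], 0.0))


# ---------------------------------------------------------------------------
# competitor extension
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompetitorModel:
    """Reduced model over (R_T, R2_T, r_T): two target mRNAs, one miRNA pool.

    The competitor mRNA carries its own binding sites for the same miRNA
    and shares the free-miRNA pool, so its only coupling to the base
    circuit is through sequestration and complexed-miRNA turnover.  With
    ``s_R2 = 0`` the competitor vanishes and the model collapses exactly
    to the base circuit.
    """

    p: MmiParameters
    q: CompetitorParameters

    def _competitor_params(self) -> MmiParameters:
        # miRNA-side multipliers of competitor complexes are taken neutral
        # (b = 1): the competitor acts through sequestration and mRNA decay.
        return MmiParameters(
            n_sites=self.q.n_sites2,
            a=self.q.a2_vec,
            b=tuple(1.0 for _ in range(self.q.n_sites2)),
            s_R=max(self.q.s_R2, 1e-300),
            k_R=self.q.k_R2,
            k_r=self.p.k_r,
            K_scaled=self.q.K2_scaled,
            binding_convention=self.p.binding_convention,
            mirna_loss_convention=self.p.mirna_loss_convention,
        )

    def solve_free(self, R_T: float, R2_T: float, r_T: float):
        """Free (R, R2, r) under the joint binding equilibrium."""
        if min(R_T, R2_T, r_T) < 0:
            raise ValueError("totals must be nonnegative")
        p2 = self._competitor_params()

        def h(r):
            phi0, psi0 = _binding_fractions(self.p, r)
            phi02, psi02 = _binding_fractions(p2, r)
            return r + R_T * psi0 / phi0 + R2_T * psi02 / phi02 - r_T

        if r_T == 0.0 or h(0.0) >= 0.0:
            r = 0.0
        else:
            r = brentq(h, 0.0, r_T, rtol=8.9e-16, maxiter=300)
        phi0, _ = _binding_fractions(self.p, r)
        phi02, _ = _binding_fractions(p2, r)
        return R_T / phi0, R2_T / phi02, r

    def rhs(self, totals, control: float | None = None):
        """Derivatives of (R_T, R2_T, r_T)."""
        R_T, R2_T, r_T = totals
        s_r = self.p.s_r if control is None else control
        p, p2 = self.p, self._competitor_params()
        R, R2, r = self.solve_free(R_T, R2_T, r_T)
        x, x2 = r / p.K_scaled, r / p2.K_scaled
        dR_T = p.s_R - p.k_R * R * P.polyval(x, p.poly_mrna_decay())
        dR2_T = self.q.s_R2 - self.q.k_R2 * R2 * P.polyval(x2, p2.poly_mrna_decay())
        dr_T = s_r - p.k_r * (
            r
            + R * P.polyval(x, p.poly_mirna_decay())
            + R2 * P.polyval(x2, p2.poly_mirna_decay())
        )
        return np.array([dR_T, dR2_T, dr_T])

    def control_at_steady_state(self, r: float) -> float:
        """miRNA synthesis rate s_r making free miRNA level ``r`` stationary."""
        p, p2 = self.p, self._competitor_params()
        x, x2 = r / p.K_scaled, r / p2.K_scaled
        g1 = (
            (p.s_R / p.k_R)
            * P.polyval(x, p.poly_mirna_decay())
            / P.polyval(x, p.poly_mrna_decay())
        )
        g2 = (
            (self.q.s_R2 / self.q.k_R2)
            * P.polyval(x2, p2.poly_mirna_decay())
            / P.polyval(x2, p2.poly_mrna_decay())
        )
        return p.k_r * (r + g1 + g2)

    def sr_curve_polys(self):
        """(numerator, denominator) of s_r(r) as polynomials in r."""
        p, p2 = self.p, self._competitor_params()
        s1 = p.K_scaled ** -np.arange(p.n_sites + 1)
        s2 = p2.K_scaled ** -np.arange(p2.n_sites + 1)
        pa1, pb1 = p.poly_mrna_decay() * s1, p.poly_mirna_decay() * s1
        pa2, pb2 = p2.poly_mrna_decay() * s2, p2.poly_mirna_decay() * s2
        den = P.polymul(pa1, pa2)
        num = P.polymul([0.0, 1.0], den)
        num = P.polyadd(num, (p.s_R / p.k_R) * P.polymul(pb1, pa2))
        num = P.polyadd(num, (self.q.s_R2 / self.q.k_R2) * P.polymul(pb2, pa1))
        return p.k_r * num, den

    def is_bistable(self, control_range=None) -> bool:
        """Does some s_r admit two stable positive steady states?"""
        from .screen import _extrema_of_curve

        ex = _extrema_of_curve(*self.sr_curve_polys())
        if len(ex) < 2:
            return False
        if control_range is not None:
            num, den = self.sr_curve_polys()
            vals = P.polyval(ex, num) / P.polyval(ex, den)
            lo, hi = control_range
            return bool(vals.min() > lo and vals.max() < hi)
        return True


def build_competitor_model(p: MmiParameters, q: CompetitorParameters) -> CompetitorModel:
    """Extend a base circuit with a competitor target mRNA."""
    return CompetitorModel(p=p, q=q)
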