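"""Cell-autonomous gene-regulatory models of the Hoxa5/Hoxc8 boundary.

Each variant describes one cell's response to the perceived RA and FGF
signals.  The wiring is declarative: transcription units combine Hill
activation/repression edges, titration pairs impose fast mRNA-miRNA
complex formation (two binding sites by default), and catalytic edges
describe conventional miRNA-mediated mRNA destabilization without
titration.

Variants
--------
``T_CR``
    Transcriptional cross-repression: Hoxa5 and Hoxc8 proteins mutually
    repress each other's transcription (canonical bistable boundary
    circuit, not supported by the epistasis data).
``T_UR``
    Unilateral repression only (Hoxc8 protein represses Hoxa5
    transcription); no feedback loop, high Hill cooperativity.
``Tmi_UR``
    T_UR plus miR-27/miR-196 acting catalytically on their targets
    (feed-forward arms; still no feedback).
``Tmi_FB``
    Tmi_UR plus hypothetical transcriptional repression of each miRNA by
    its target's protein (TF-miRNA double-negative feedback).
``mmi_S``
    The titration model: miR-27 and miR-196 form 1:1 and 1:2 complexes
    with the Hoxa5 and Hoxc8 mRNAs; unbalanced complex degradation makes
    each pair a bistable switch.  Proteins are translated from free
    mRNA, so protein patterns can segregate sharply while total mRNA
    patterns overlap.
``mmi_S_nofeedback``
    mmi_S with balanced complex degradation (a_i/b_i ratios equal):
    titration without the hidden feedback, hence no bistable switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import polynomial as P

from ..parameters import MmiParameters

__all__ = [
    "HillEdge",
    "TranscriptionUnit",
    "TitrationPair",
    "CatalyticEdge",
    "CellModelSpec",
    "cell_model",
    "VARIANTS",
]

MIRNA_ALIASES = {"miR-27": "m27", "miR-196": "m196", "m27": "m27", "m196": "m196"}


@dataclass(frozen=True)
class HillEdge:
    regulator: str  # "RA", "FGF" or a protein species
    kind: str  # "activator" | "repressor"
    theta: float
    n: float = 2.0
    floor: float = 0.0  # residual transmission of a repressed promoter

    def value(self, level):
        level = np.maximum(level, 0.0)
        h = level**self.n / (level**self.n + self.theta**self.n)
        if self.kind == "activator":
            return h
        return self.floor + (1.0 - self.floor) * (1.0 - h)


@dataclass(frozen=True)
class TranscriptionUnit:
    """rate = (basal + induced * prod activators) * prod repressors."""

    basal: float
    induced: float = 0.0
    edges: tuple[HillEdge, ...] = ()

    def rate(self, levels: dict):
        act, rep = 1.0, 1.0
        for e in self.edges:
            v = e.value(levels[e.regulator])
            if e.kind == "activator":
                act = act * v
            else:
                rep = rep * v
        return (self.basal + self.induced * act) * rep


@dataclass(frozen=True)
class TitrationPair:
    mrna: str
    mirna: str
    a: tuple[float, ...] = (1.0, 1.0)
    b: tuple[float, ...] = (1.0, 0.1)
    K_scaled: float = 1e-4
    binding_convention: str = "statistical_factors"

    def kinetics(self, s_R: float = 1.0, s_r: float = 1.0) -> MmiParameters:
        return MmiParameters(
            n_sites=len(self.a),
            a=self.a,
            b=self.b,
            s_R=s_R,
            s_r=s_r,
            K_scaled=self.K_scaled,
            binding_convention=self.binding_convention,
        )


@dataclass(frozen=True)
class CatalyticEdge:
    mirna: str
    mrna: str
    k_cat: float = 2.0
    theta_tl: float = 0.5  # translational inhibition scale


@dataclass(frozen=True)
class CellModelSpec:
    variant: str
    transcription: dict[str, TranscriptionUnit]  # mRNA and miRNA totals
    translation: dict[str, str]  # protein -> source mRNA
    pairs: tuple[TitrationPair, ...] = ()
    catalytic: tuple[CatalyticEdge, ...] = ()
    k_R: float = 1.0
    k_r: float = 1.0
    k_tl: float = 1.0
    k_p: float = 1.0

    @property
    def mrna_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.transcription if s.startswith("R"))

    @property
    def mirna_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.transcription if s.startswith("m"))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.transcription) + tuple(self.translation)

    def pair_for(self, mrna: str) -> TitrationPair | None:
        for pr in self.pairs:
            if pr.mrna == mrna:
                return pr
        return None

    # ------------------------------------------------------------------
    # vectorized dynamics
    # ------------------------------------------------------------------

    def free_species(self, state: dict, cache: dict | None = None) -> dict:
        """Free mRNA/miRNA levels implied by the fast binding equilibrium.

        Totals of non-titration species pass through unchanged.  For each
        titration pair the free miRNA solves the conservation equation by
        warm-started Newton iteration (the map is monotone in free
        miRNA), vectorized over all cells.
        """
        free = {}
        for s in self.transcription:
            free[s] = state[s]
        for pr in self.pairs:
            RT = np.asarray(state[pr.mrna], dtype=float)
            rT = np.asarray(state[pr.mirna], dtype=float)
            r = _pair_free_mirna(pr, RT, rT, cache)
            x = r / pr.K_scaled
            kin = pr.kinetics()
            phi0 = P.polyval(x, kin.poly_occupancy())
            free[pr.mrna] = RT / phi0
            free[pr.mirna] = r
        return free

    def rhs(self, state: dict, ra, fgf, cache: dict | None = None) -> dict:
        levels = dict(state)
        levels["RA"] = ra
        levels["FGF"] = fgf
        free = self.free_species(state, cache)

        d = {}
        for s, unit in self.transcription.items():
            syn = unit.rate(levels)
            if s.startswith("R"):
                pr = self.pair_for(s)
                if pr is not None:
                    x = free[pr.mirna] / pr.K_scaled
                    decay = self.k_R * free[s] * P.polyval(x, pr.kinetics().poly_mrna_decay())
                else:
                    decay = self.k_R * state[s]
                d[s] = syn - decay
            else:
                pr = next((q for q in self.pairs if q.mirna == s), None)
                if pr is not None:
                    x = free[s] / pr.K_scaled
                    bound_decay = free[pr.mrna] * P.polyval(x, pr.kinetics().poly_mirna_decay())
                    d[s] = syn - self.k_r * (free[s] + bound_decay)
                else:
                    d[s] = syn - self.k_r * state[s]
        for edge in self.catalytic:
            d[edge.mrna] = d[edge.mrna] - edge.k_cat * state[edge.mirna] * state[edge.mrna]
        for prot, mrna in self.translation.items():
            syn = self.k_tl * free[mrna]
            for edge in self.catalytic:
                if edge.mrna == mrna:
                    syn = syn / (1.0 + state[edge.mirna] / edge.theta_tl)
            d[prot] = syn - self.k_p * state[prot]
        return d

    def knockout(self, mirna: str) -> "CellModelSpec":
        """Turn off production of the named miRNA in all cells (idempotent)."""
        name = MIRNA_ALIASES.get(mirna, mirna)
        if name not in self.transcription or not name.startswith("m"):
            raise KeyError(f"unknown miRNA species {mirna!r} in variant {self.variant}")
        tr = dict(self.transcription)
        tr[name] = replace(tr[name], basal=0.0, induced=0.0)
        return replace(self, transcription=tr)


def _pair_free_mirna(pr: TitrationPair, RT, rT, cache: dict | None):
    """Vectorized solve of r + RT*psi0(r/K)/phi0(r/K) = rT for free miRNA."""
    kin = pr.kinetics()
    c_occ, c_bnd = kin.poly_occupancy(), kin.poly_bound()
    key = (pr.mrna, pr.mirna)
    r = None
    if cache is not None and key in cache and cache[key].shape == rT.shape:
        r = np.minimum(cache[key], rT)
    if r is None:
        r = 0.5 * rT
    K = pr.K_scaled
    d_occ, d_bnd = P.polyder(c_occ), P.polyder(c_bnd)
    for _ in range(60):
        x = r / K
        phi0 = P.polyval(x, c_occ)
        psi0 = P.polyval(x, c_bnd)
        dphi0 = P.polyval(x, d_occ) / K
        dpsi0 = P.polyval(x, d_bnd) / K
        f = r + RT * psi0 / phi0 - rT
        fp = 1.0 + RT * (dpsi0 * phi0 - psi0 * dphi0) / phi0**2
        r = np.clip(r - f / fp, 0.0, rT)
        if np.all(np.abs(f) <= 1e-10 * (1.0 + rT)):
            break
    if cache is not None:
        cache[key] = r.copy()
    return r


# ---------------------------------------------------------------------------
# default parameterizations
# ---------------------------------------------------------------------------

# Morphogen sensing: half-maximal response deep in each gradient's tail so
# that the receded (low-plateau) gradients still carry positional
# information while the transient pulse reaches past the domain midpoint.
THETA_RA = 0.04
THETA_FGF = 0.04
#: residual transmission of the Hoxc8-repressed Hoxa5 promoter
REPRESSION_FLOOR = 0.25


def _t_cr() -> CellModelSpec:
    # basal transcription keeps the cross-repression switch bistable after
    # the morphogens recede, so pulse-era commitments are remembered
    tr = {
        "Ra": TranscriptionUnit(
            basal=0.6,
            induced=2.0,
            edges=(
                HillEdge("RA", "activator", THETA_RA, 2),
                HillEdge("Pc", "repressor", 0.3, 4),
            ),
        ),
        "Rc": TranscriptionUnit(
            basal=0.6,
            induced=2.0,
            edges=(
                HillEdge("FGF", "activator", THETA_FGF, 2),
                HillEdge("Pa", "repressor", 0.3, 4),
            ),
        ),
    }
    return CellModelSpec("T_CR", tr, {"Pa": "Ra", "Pc": "Rc"})


def _t_ur() -> CellModelSpec:
    # no feedback loop; "very high cooperativity" of the single repression
    tr = {
        "Ra": TranscriptionUnit(
            basal=0.1,
            induced=2.0,
            edges=(
                HillEdge("RA", "activator", THETA_RA, 4),
                HillEdge("Pc", "repressor", 0.3, 4),
            ),
        ),
        "Rc": TranscriptionUnit(
            basal=0.1,
            induced=2.0,
            edges=(HillEdge("FGF", "activator", THETA_FGF, 4),),
        ),
    }
    return CellModelSpec("T_UR", tr, {"Pa": "Ra", "Pc": "Rc"})


def _tmi_ur() -> CellModelSpec:
    base = _t_ur()
    tr = dict(base.transcription)
    tr["m27"] = TranscriptionUnit(basal=0.4)
    tr["m196"] = TranscriptionUnit(
        basal=0.4, induced=0.2, edges=(HillEdge("FGF", "activator", THETA_FGF, 2),)
    )
    return replace(
        base,
        variant="Tmi_UR",
        transcription=tr,
        catalytic=(
            CatalyticEdge("m27", "Ra", k_cat=5.0, theta_tl=0.2),
            CatalyticEdge("m196", "Rc", k_cat=5.0, theta_tl=0.2),
        ),
    )


def _tmi_fb() -> CellModelSpec:
    base = _tmi_ur()
    tr = dict(base.transcription)
    tr["Ra"] = replace(tr["Ra"], basal=0.6)
    tr["Rc"] = replace(tr["Rc"], basal=0.6)
    tr["m27"] = replace(tr["m27"], edges=(HillEdge("Pa", "repressor", 0.15, 2),))
    tr["m196"] = replace(
        tr["m196"], edges=tr["m196"].edges + (HillEdge("Pc", "repressor", 0.15, 2),)
    )
    return replace(base, variant="Tmi_FB", transcription=tr)


def _mmi_s(feedback: bool = True) -> CellModelSpec:
    # cooperative-miRNA-degradation kinetics: the 1:2 complex protects the
    # miRNA (b2 < b1), so total mRNA is untouched by the switch while free
    # mRNA drops sharply; balanced kinetics remove the switch.
    kin = dict(a=(1.0, 1.0), b=(1.0, 0.1)) if feedback else dict(a=(1.0, 1.0), b=(1.0, 1.0))
    tr = {
        "Ra": TranscriptionUnit(
            basal=0.25,
            induced=3.2,
            edges=(
                HillEdge("RA", "activator", THETA_RA, 2),
                HillEdge("Pc", "repressor", 0.1, 2, floor=REPRESSION_FLOOR),
            ),
        ),
        "Rc": TranscriptionUnit(
            basal=0.15,
            induced=3.0,
            edges=(HillEdge("FGF", "activator", THETA_FGF, 2),),
        ),
        "m27": TranscriptionUnit(basal=0.15),
        "m196": TranscriptionUnit(
            basal=0.1, induced=0.52, edges=(HillEdge("FGF", "activator", THETA_FGF, 2),)
        ),
    }
    pairs = (
        TitrationPair("Ra", "m27", **kin),
        TitrationPair("Rc", "m196", **kin),
    )
    return CellModelSpec(
        "mmi_S" if feedback else "mmi_S_nofeedback",
        tr,
        {"Pa": "Ra", "Pc": "Rc"},
        pairs=pairs,
    )


VARIANTS = ("T_CR", "T_UR", "Tmi_UR", "Tmi_FB", "mmi_S", "mmi_S_nofeedback")


def cell_model(variant: str) -> CellModelSpec:
    """Default parameterization of a named model variant."""
    factories = {
        "T_CR": _t_cr,
        "T_UR": _t_ur,
        "Tmi_UR": _tmi_ur,
        "Tmi_FB": _tmi_fb,
        "mmi_S": lambda: _mmi_s(True),
        "mmi_S_nofeedback": lambda: _mmi_s(False),
    }
    if variant not in factories:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    return factories[variant]()
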