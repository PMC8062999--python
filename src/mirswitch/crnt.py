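"""Chemical reaction network structure of the titration circuits.

Computes the classical structural indices: number of complexes,
linkage classes (connected components of the complex graph), rank of the
stoichiometric matrix over the integers, and the deficiency
``delta = n_complexes - n_linkage_classes - rank``.  The deficiency-zero
and deficiency-one theorems then constrain the network's capacity for
multistationarity regardless of rate constants.

The canonical construction writes complex degradation as elementary
recycling steps (degradation of one partner releases the survivor), and
uses a single shared empty complex for all synthesis and decay reactions.
The indices of such a network depend on this bookkeeping: writing the
1:1 complex's mRNA-decay as ``C1 -> r`` merges linkage classes that stay
separate under other notations, so published deficiency values for the
same chemistry can differ from the canonical ones reported here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import sympy

from .parameters import MmiParameters

__all__ = ["ReactionNetwork", "DeficiencyReport", "build_network", "deficiency", "weak_reversibility"]

Complex = tuple[tuple[str, int], ...]  # sorted ((species, count), ...); () is empty


def _cplx(d: dict[str, int] | Iterable[tuple[str, int]]) -> Complex:
    items = d.items() if isinstance(d, dict) else d
    return tuple(sorted((s, int(c)) for s, c in items if c > 0))


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]
    complexes: tuple[Complex, ...]
    reactions: tuple[tuple[int, int], ...]  # (reactant complex idx, product idx)

    def __post_init__(self):
        for i, j in self.reactions:
            if i == j:
                raise ValueError("self-loop reactions are not allowed")
            if not (0 <= i < len(self.complexes) and 0 <= j < len(self.complexes)):
                raise ValueError("reaction endpoint is not a registered complex")

    def complex_vector(self, idx: int):
        v = {s: 0 for s in self.species}
        for s, c in self.complexes[idx]:
            v[s] = c
        return [v[s] for s in self.species]


@dataclass(frozen=True)
class DeficiencyReport:
    n_complexes: int
    n_linkage_classes: int
    stoich_rank: int
    deficiency: int
    weakly_reversible: bool


def build_network(p: MmiParameters | int) -> ReactionNetwork:
    """Canonical network for an n-site circuit.

    Reactions: synthesis/decay of both free species, stepwise
    binding/unbinding, and per-complex degradation events in which the
    decayed partner's survivor is released intact.  Count:
    ``4 + 2n (binding) + 2n (complex degradations)``.
    """
    n = p if isinstance(p, int) else p.n_sites
    if n not in (1, 2, 3):
        raise ValueError("n_sites must be 1, 2 or 3")

    species = ["R", "r"] + [f"C{i}" for i in range(1, n + 1)]
    complexes: list[Complex] = []
    index: dict[Complex, int] = {}

    def cx(d) -> int:
        key = _cplx(d)
        if key not in index:
            index[key] = len(complexes)
            complexes.append(key)
        return index[key]

    def bound(i: int) -> dict:
        return {"R": 1} if i == 0 else {f"C{i}": 1}

    rxns: list[tuple[int, int]] = []
    empty = cx({})
    rxns += [(empty, cx({"R": 1})), (cx({"R": 1}), empty)]
    rxns += [(empty, cx({"r": 1})), (cx({"r": 1}), empty)]
    for i in range(1, n + 1):
        lhs = cx({**bound(i - 1), "r": bound(i - 1).get("r", 0) + 1})
        rhs = cx(bound(i))
        rxns += [(lhs, rhs), (rhs, lhs)]
    for i in range(1, n + 1):
        # mRNA decays inside C_i: the i bound miRNAs are recycled
        rxns.append((cx(bound(i)), cx({"r": i})))
        # one bound miRNA decays: C_i -> C_{i-1}
        rxns.append((cx(bound(i)), cx(bound(i - 1))))
    return ReactionNetwork(tuple(species), tuple(complexes), tuple(rxns))


def deficiency(net: ReactionNetwork) -> DeficiencyReport:
    """Structural indices with the rank taken in exact integer arithmetic."""
    g = nx.Graph()
    g.add_nodes_from(range(len(net.complexes)))
    g.add_edges_from(net.reactions)
    n_link = nx.number_connected_components(g)

    cols = []
    for i, j in net.reactions:
        vi, vj = net.complex_vector(i), net.complex_vector(j)
        cols.append([b - a for a, b in zip(vi, vj)])
    rank = sympy.Matrix(cols).T.rank() if cols else 0

    d = len(net.complexes) - n_link - rank
    assert d >= 0, "deficiency must be nonnegative"
    return DeficiencyReport(
        n_complexes=len(net.complexes),
        n_linkage_classes=n_link,
        stoich_rank=int(rank),
        deficiency=int(d),
        weakly_reversible=weak_reversibility(net),
    )


def weak_reversibility(net: ReactionNetwork) -> bool:
    """True iff every reaction lies on a directed cycle of the complex graph,
    i.e. both endpoints share a strongly connected component."""
    dg = nx.DiGraph()
    dg.add_nodes_from(range(len(net.complexes)))
    dg.add_edges_from(net.reactions)
    scc_of = {}
    for k, comp in enumerate(nx.strongly_connected_components(dg)):
        for node in comp:
            scc_of[node] = k
    return all(scc_of[i] == scc_of[j] for i, j in net.reactions)
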