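"""Kinetic parameter records for mRNA-miRNA titration circuits.

The circuit couples one mRNA species (``R``) carrying ``n_sites`` binding
sites for one miRNA species (``r``).  Bound states are 1:i complexes
``C_i`` (one mRNA, i miRNAs).  Rates are nondimensionalized so that
concentrations are measured in units of ``s_R / k_R`` and time in units of
``1 / k_R``; the dissociation constant then enters only through the scaled
combination ``K_scaled = K * k_R / s_R``.

Two modelling conventions are explicit:

``binding_convention``
    ``"statistical_factors"`` (default): the i-th stepwise binding carries
    the combinatorial multiplicity of i identical sites, so at equilibrium
    ``C_i = binom(n, i) * R * (r/K)**i``.  ``"plain"``: a single stepwise
    dissociation constant with no multiplicity, ``C_i = R * (r/K)**i``.

``mirna_loss_convention``
    ``"per_molecule"`` (default): each miRNA bound in ``C_i`` decays
    independently at rate ``b_i * k_r``, so the complex loses miRNA at
    total rate ``i * b_i * k_r``.  ``"per_complex"``: the complex loses
    one miRNA at total rate ``b_i * k_r`` regardless of occupancy.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace
from math import comb
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "MmiParameters",
    "CompetitorParameters",
    "FullState",
    "ReducedState",
    "load_parameters",
    "save_parameters",
]

_BINDING_CONVENTIONS = ("plain", "statistical_factors")
_LOSS_CONVENTIONS = ("per_molecule", "per_complex")


@dataclass(frozen=True)
class MmiParameters:
    """Kinetic constants of an n-site mRNA-miRNA circuit.

    Parameters
    ----------
    n_sites
        Number of miRNA binding sites on the mRNA (1, 2 or 3).
    a
        Relative mRNA degradation multipliers ``a_1..a_n``: the mRNA inside
        the 1:i complex degrades at ``a_i * k_R``.
    b
        Relative miRNA degradation multipliers ``b_1..b_n``: each miRNA
        bound in the 1:i complex degrades at ``b_i * k_r``.
    s_R, s_r
        mRNA and miRNA synthesis rates.  ``s_r`` is the usual control
        parameter for bifurcation analysis.
    k_R, k_r
        Basal (free-form) degradation rate constants.
    K_scaled
        Scaled stepwise dissociation constant ``K * k_R / s_R``.
    """

    n_sites: int
    a: tuple[float, ...]
    b: tuple[float, ...]
    s_R: float = 1.0
    s_r: float = 1.0
    k_R: float = 1.0
    k_r: float = 1.0
    K_scaled: float = 1e-5
    binding_convention: str = "statistical_factors"
    mirna_loss_convention: str = "per_molecule"

    def __post_init__(self):
        if self.n_sites not in (1, 2, 3):
            raise ValueError(f"n_sites must be 1, 2 or 3, got {self.n_sites}")
        object.__setattr__(self, "a", tuple(float(v) for v in self.a))
        object.__setattr__(self, "b", tuple(float(v) for v in self.b))
        if len(self.a) != self.n_sites or len(self.b) != self.n_sites:
            raise ValueError("a and b must each have length n_sites")
        for name in ("s_R", "s_r", "k_R", "k_r", "K_scaled"):
            if getattr(self, name) < 0 or (name != "s_r" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if any(v <= 0 for v in self.a) or any(v <= 0 for v in self.b):
            raise ValueError("degradation multipliers must be strictly positive")
        if self.binding_convention not in _BINDING_CONVENTIONS:
            raise ValueError(f"unknown binding_convention {self.binding_convention!r}")
        if self.mirna_loss_convention not in _LOSS_CONVENTIONS:
            raise ValueError(f"unknown mirna_loss_convention {self.mirna_loss_convention!r}")

    # -- convention-derived coefficient vectors (index i-1 <-> complex C_i) --

    @property
    def site_multiplicity(self) -> tuple[int, ...]:
        """Combinatorial factor c_i in the equilibrium C_i = c_i R (r/K)^i."""
        if self.binding_convention == "statistical_factors":
            return tuple(comb(self.n_sites, i) for i in range(1, self.n_sites + 1))
        return tuple(1 for _ in range(self.n_sites))

    @property
    def mirna_loss_weight(self) -> tuple[int, ...]:
        """Factor lambda_i multiplying b_i k_r in the miRNA loss from C_i."""
        if self.mirna_loss_convention == "per_molecule":
            return tuple(range(1, self.n_sites + 1))
        return tuple(1 for _ in range(self.n_sites))

    # Polynomials in the occupancy variable x = r / K_scaled, ascending order.

    def poly_occupancy(self) -> np.ndarray:
        """phi_0(x) = 1 + sum_i c_i x^i  (total mRNA per unit free mRNA)."""
        c = self.site_multiplicity
        return np.array([1.0] + [c[i] for i in range(self.n_sites)], dtype=float)

    def poly_bound(self) -> np.ndarray:
        """psi_0(x) = sum_i i c_i x^i  (bound miRNA per unit free mRNA)."""
        c = self.site_multiplicity
        return np.array([0.0] + [(i + 1) * c[i] for i in range(self.n_sites)], dtype=float)

    def poly_mrna_decay(self) -> np.ndarray:
        """phi_a(x) = 1 + sum_i a_i c_i x^i  (effective mRNA decay weight)."""
        c = self.site_multiplicity
        return np.array([1.0] + [self.a[i] * c[i] for i in range(self.n_sites)], dtype=float)

    def poly_mirna_decay(self) -> np.ndarray:
        """psi_b(x) = sum_i lambda_i b_i c_i x^i  (complexed miRNA decay weight)."""
        c = self.site_multiplicity
        lam = self.mirna_loss_weight
        return np.array(
            [0.0] + [lam[i] * self.b[i] * c[i] for i in range(self.n_sites)], dtype=float
        )

    def with_control(self, s_r: float) -> "MmiParameters":
        return replace(self, s_r=float(s_r))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["a"] = list(self.a)
        d["b"] = list(self.b)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MmiParameters":
        return cls(**d)


@dataclass(frozen=True)
class CompetitorParameters:
    """A second (competitor) target mRNA sharing the free miRNA pool."""

    n_sites2: int
    a2_vec: tuple[float, ...]
    s_R2: float = 0.1
    k_R2: float = 1.0
    K2_scaled: float = 1e-5

    def __post_init__(self):
        if self.n_sites2 not in (1, 2, 3):
            raise ValueError(f"n_sites2 must be 1, 2 or 3, got {self.n_sites2}")
        object.__setattr__(self, "a2_vec", tuple(float(v) for v in self.a2_vec))
        if len(self.a2_vec) != self.n_sites2:
            raise ValueError("a2_vec must have length n_sites2")
        if self.s_R2 < 0 or self.k_R2 <= 0 or self.K2_scaled <= 0:
            raise ValueError("competitor rates must be positive (s_R2 may be zero)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["a2_vec"] = list(self.a2_vec)
        return d


@dataclass(frozen=True)
class FullState:
    """Species-resolved state: free mRNA, free miRNA and 1:i complexes."""

    R: float
    r: float
    C: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "C", tuple(float(v) for v in self.C))
        if self.R < 0 or self.r < 0 or any(v < 0 for v in self.C):
            raise ValueError("all components of a FullState must be nonnegative")

    @property
    def total_mrna(self) -> float:
        return self.R + sum(self.C)

    @property
    def total_mirna(self) -> float:
        return self.r + sum((i + 1) * c for i, c in enumerate(self.C))

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.r, *self.C], dtype=float)


@dataclass(frozen=True)
class ReducedState:
    """Total-species state (R_T, r_T) of the reduced (tQSSA) model."""

    R_T: float
    r_T: float

    def __post_init__(self):
        if self.R_T < 0 or self.r_T < 0:
            raise ValueError("totals must be nonnegative")


def save_parameters(p: MmiParameters, path) -> None:
    """Serialize a parameter record to a flat YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_dict(), fh, sort_keys=True)


def load_parameters(path) -> MmiParameters:
    with open(path) as fh:
        return MmiParameters.from_dict(yaml.safe_load(fh))
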