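"""Boundary metrics and fate calls for tissue simulations.

Fate calls use per-protein "on" thresholds, by default a fixed fraction
of that protein's maximum over the grid in the analysed snapshot (the
thresholds actually applied are recorded in the returned object).  A
cell's lineage decision is *equivocal* when it is double-positive, when
both proteins are sub-threshold, or when its Hoxa5/Hoxc8 protein ratio
is within the ambiguity fold of unity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FateThresholds",
    "FateCall",
    "fate_call",
    "transition_width",
    "segregation_index",
    "mrna_overlap_band",
    "boundary_position",
]

A5ON_C8OFF = "A5on_C8off"

A5OFF_C8ON = "A5off_C8on"
DOUBLE_ON = "double_on"
DOUBLE_OFF = "double_off"


@dataclass(frozen=True)
class FateThresholds:
    on_fraction: float = 0.1  # "on" above this fraction of the protein's grid max
    ratio_fold: float = 10.0  # unequivocal if proteins differ by at least this fold
    theta_a: float | None = None  # absolute overrides
    theta_c: float | None = None

    def resolve(self, Pa: np.ndarray, Pc: np.ndarray) -> tuple[float, float]:
        ta = self.theta_a if self.theta_a is not None else self.on_fraction * float(Pa.max())
        tc = self.theta_c if self.theta_c is not None else self.on_fraction * float(Pc.max())
        return max(ta, 1e-12), max(tc, 1e-12)


#: absolute thresholds for the titration (mmi_S-family) analyses: the
#: Hoxa5 basal leak under Hoxc8 repression sits near 0.1, so the Hoxa5
#: "on" call is set below it; the Hoxc8 call sits above the constitutive
#: Hoxc8 leak.  Recorded with every fate call that uses them.
MMI_S_THRESHOLDS = FateThresholds(theta_a=0.05, theta_c=0.2)


@dataclass
class FateCall:
    labels: np.ndarray  # (n_columns, n_positions) of label strings
    theta_a: float
    theta_c: float
    thresholds: FateThresholds

    def count(self, label: str) -> int:
        return int((self.labels == label).sum())

    def position_has(self, label: str) -> np.ndarray:
        return (self.labels == label).any(axis=0)


def fate_call(
    Pa: np.ndarray, Pc: np.ndarray, thresholds: FateThresholds | None = None
) -> FateCall:
    th = thresholds or FateThresholds()
    ta, tc = th.resolve(Pa, Pc)
    on_a, on_c = Pa >= ta, Pc >= tc
    labels = np.full(Pa.shape, DOUBLE_OFF, dtype=object)
    labels[on_a & ~on_c] = A5ON_C8OFF
    labels[~on_a & on_c] = A5OFF_C8ON
    labels[on_a & on_c] = DOUBLE_ON
    return FateCall(labels=labels, theta_a=ta, theta_c=tc, thresholds=th)


def _equivocal(Pa, Pc, call: FateCall) -> np.ndarray:
    ratio = (Pa + 1e-12) / (Pc + 1e-12)
    fold = call.thresholds.ratio_fold
    ambiguous_ratio = (ratio < fold) & (ratio > 1.0 / fold)
    single = (call.labels == A5ON_C8OFF) | (call.labels == A5OFF_C8ON)
    return ~single | ambiguous_ratio


def transition_width(
    Pa: np.ndarray, Pc: np.ndarray, thresholds: FateThresholds | None = None
) -> int:
    """Number of rostrocaudal positions with >= 1 equivocal cell."""
    call = fate_call(Pa, Pc, thresholds)
    eq = _equivocal(Pa, Pc, call)
    return int(eq.any(axis=0).sum())


def boundary_position(
    Pa: np.ndarray, Pc: np.ndarray, thresholds: FateThresholds | None = None
) -> float:
    """Midpoint between the caudal edge of the Hoxa5 domain and the rostral
    edge of the Hoxc8 domain (column-majority vote per position)."""
    call = fate_call(Pa, Pc, thresholds)
    a_majority = (call.labels == A5ON_C8OFF).mean(axis=0) > 0.5
    c_majority = (call.labels == A5OFF_C8ON).mean(axis=0) > 0.5
    a_end = float(np.max(np.nonzero(a_majority)[0])) if a_majority.any() else -1.0
    c_start = float(np.min(np.nonzero(c_majority)[0])) if c_majority.any() else float(Pa.shape[1])
    return 0.5 * (a_end + c_start)


def segregation_index(
    mrna_profile: np.ndarray, protein_profile: np.ndarray
) -> float:
    """Protein-to-mRNA ratio of boundary steepness along the RC axis.

    Both inputs are 1-d rostrocaudal profiles (column averages); each is
    max-normalized, the steepness is the maximum absolute discrete
    spatial derivative, and the index is protein steepness over mRNA
    steepness.  > 1 means the protein boundary is sharper than the mRNA
    boundary.
    """
    m = np.asarray(mrna_profile, dtype=float)
    p = np.asarray(protein_profile, dtype=float)
    if m.max() <= 0 or p.max() <= 0 or np.ptp(m) < 1e-9 * m.max() or np.ptp(p) < 1e-9 * p.max():
        raise ValueError("flat profile: segregation index undefined")
    sm = float(np.abs(np.diff(m / m.max())).max())
    sp = float(np.abs(np.diff(p / p.max())).max())
    return sp / sm


def mrna_overlap_band(
    Ra_total: np.ndarray,
    Rc_total: np.ndarray,
    on_fraction: float = 0.1,
    absolute: float | None = None,
) -> np.ndarray:
    """Positions whose column-averaged total mRNAs are both above
    threshold: ``absolute`` (same units as the totals) when given,
    otherwise ``on_fraction`` of the respective profile maximum."""
    ra = Ra_total.mean(axis=0)
    rc = Rc_total.mean(axis=0)
    if absolute is not None:
        return (ra >= absolute) & (rc >= absolute)
    return (ra >= on_fraction * ra.max()) & (rc >= on_fraction * rc.max())
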