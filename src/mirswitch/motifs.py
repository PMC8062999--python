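"""Counting multi-site mRNA-miRNA motifs in target-site catalogs.

A two-site (or three-site) titration switch needs one mRNA carrying k
binding sites for the same miRNA family.  Given a predicted target-site
table (TargetScan-style TSV), two bounds on the number of such motif
instances are computed:

* a lower bound — (gene, family) pairs with at least k *conserved* sites;
* an upper bound — the number of distinct k-subsets of sites (conserved
  or not) sharing gene and family, ``sum over groups of C(m, k)``.

miRNAs are grouped at the family level and overlapping sites are not
merged; counting is invariant to row order and duplicated rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "SiteCatalog",
    "MotifCounts",
    "read_site_catalog",
    "write_site_catalog",
    "count_motifs",
    "generate_catalog",
    "TARGETSCAN_DIALECT",
]

log = logging.getLogger(__name__)

REQUIRED = ["gene_id", "transcript_id", "mirna_family", "site_start", "site_end", "conserved"]

#: column-name mapping for TargetScan "predicted targets" site tables
TARGETSCAN_DIALECT = {
    "Gene Symbol": "gene_id",
    "Transcript ID": "transcript_id",
    "miR Family": "mirna_family",
    "UTR start": "site_start",
    "UTR end": "site_end",
    "Site type": "site_type",
    "PCT": "pct",
}


@dataclass
class SiteCatalog:
    """Validated, deduplicated table of predicted miRNA binding sites."""

    frame: pd.DataFrame
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class MotifCounts:
    k: int
    pair_count_lower: int
    tuple_count_upper: int


def _validate(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    df = df.copy()
    start = pd.to_numeric(df["site_start"], errors="coerce")
    end = pd.to_numeric(df["site_end"], errors="coerce")
    ok = start.notna() & end.notna() & (start > 0) & (start < end)
    bad = int((~ok).sum())
    if bad:
        log.warning("rejected %d malformed site rows", bad)
    df = df[ok].copy()
    df["site_start"] = start[ok].astype(int)
    df["site_end"] = end[ok].astype(int)
    df["conserved"] = df["conserved"].map(
        lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v).strip().lower()
        in ("1", "true", "yes", "y")
    )
    before = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    return df, bad + (before - len(df)) * 0  # duplicates are dropped, not "rejected"


def read_site_catalog(path, dialect: dict[str, str] | None = None) -> SiteCatalog:
    """Read a tab-separated site table.

    ``dialect`` maps source column names onto the canonical schema
    (see :data:`TARGETSCAN_DIALECT`).  Rows with unparseable or inverted
    coordinates are rejected and logged; duplicates are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect:
        df = df.rename(columns=dialect)
    if "site_type" not in df.columns:
        df["site_type"] = ""
    df["site_type"] = df["site_type"].fillna("")
    if "conserved" not in df.columns:
        raise ValueError("missing required column 'conserved' (map it via the dialect)")
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df[REQUIRED + ["site_type"]]
    frame, rejected = _validate(df)
    log.info("loaded %d site rows (%d rejected)", len(frame), rejected)
    return SiteCatalog(frame=frame, n_rejected=rejected)


def write_site_catalog(cat: SiteCatalog, path) -> None:
    cat.frame.to_csv(path, sep="\t", index=False)


def count_motifs(cat: SiteCatalog, k: int) -> MotifCounts:
    """Lower/upper bounds on k-site motif instances (k = 2 or 3)."""
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    df = cat.frame.drop_duplicates()
    if df.empty:
        return MotifCounts(k=k, pair_count_lower=0, tuple_count_upper=0)
    keys = ["gene_id", "mirna_family"]
    cons = df[df["conserved"]].groupby(keys).size()
    lower = int((cons >= k).sum())
    sizes = df.groupby(keys).size()
    upper = int(sum(comb(int(m), k) for m in sizes if m >= k))
    return MotifCounts(k=k, pair_count_lower=lower, tuple_count_upper=upper)


def generate_catalog(
    n_genes: int,
    n_families: int,
    site_count_distribution=("poisson", 0.2),
    conserved_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[SiteCatalog, dict[int, MotifCounts]]:
    """Synthetic site catalog with ground-truth motif counts.

    Each (gene, family) pair receives a site count drawn from the given
    distribution — ``("poisson", lam)``, ``("fixed", m)`` or a callable
    ``f(rng) -> int`` — and each site is conserved with the given
    probability.  The true lower/upper bounds for k = 2 and 3 are tallied
    by direct bookkeeping while the rows are generated, independently of
    :func:`count_motifs`.
    """
    if not 0.0 <= conserved_fraction <= 1.0:
        raise ValueError("conserved_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    if callable(site_count_distribution):
        draw = site_count_distribution
    else:
        kind, val = site_count_distribution
        if kind == "poisson":
            draw = lambda g: int(g.poisson(val))
        elif kind == "fixed":
            draw = lambda g: int(val)
        else:
            raise ValueError(f"unknown site count distribution {kind!r}")

    rows = []
    truth = {2: [0, 0], 3: [0, 0]}  # k -> [lower, upper]
    for gi in range(n_genes):
        gene = f"G{gi:05d}"
        for fi in range(n_families):
            fam = f"miR-F{fi:03d}"
            m = draw(rng)
            if m == 0:
                continue
            conserved = rng.random(m) < conserved_fraction
            pos = np.sort(rng.choice(np.arange(1, 5000), size=m, replace=False))
            for s, c in zip(pos, conserved):
                rows.append((gene, f"{gene}.1", fam, int(s), int(s) + 7, "", bool(c)))
            n_cons = int(conserved.sum())
            for k in (2, 3):
                truth[k][0] += n_cons >= k
                truth[k][1] += comb(m, k) if m >= k else 0

    frame = pd.DataFrame(
        rows,
        columns=["gene_id", "transcript_id", "mirna_family", "site_start", "site_end", "site_type", "conserved"],
    )
    counts = {
        k: MotifCounts(k=k, pair_count_lower=truth[k][0], tuple_count_upper=truth[k][1])
        for k in (2, 3)
    }
    return SiteCatalog(frame=frame[REQUIRED + ["site_type"]]), counts
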