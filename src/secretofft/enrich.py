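"""Local pathway over-representation analysis (ORA).

Pathway sets come from a GMT file; the test is the one-sided upper-tail
hypergeometric (the standard over-representation model): drawing |query|
proteins from the background with |pathway| successes, the p-value is
P(X >= found).  Multiple testing is controlled with Benjamini-Hochberg
FDR by default.  The background universe defaults to the union of all
pathway members, but supplying the experiment's own identified-protein
universe is recommended.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["PathwayDB", "EnrichmentRow", "read_gmt", "write_gmt", "hypergeom_enrich", "bh_fdr"]


@dataclass
class PathwayDB:
    """Named protein sets over a declared background universe."""

    pathways: dict  # id -> (name, frozenset of members)
    background: frozenset

    def __post_init__(self) -> None:
        for pid, (_, members) in self.pathways.items():
            if not members <= self.background:
                raise ValueError(f"pathway {pid} has members outside the background")


@dataclass
class EnrichmentRow:
    pathway_id: str
    pathway_name: str
    found: int
    total: int
    pvalue: float
    fdr: float


def read_gmt(path, background: set | None = None) -> PathwayDB:
    """Parse a GMT file (``id<TAB>description<TAB>member...`` per line)."""
    pathways: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (need id, description, >=1 member)")
            pid, desc, members = parts[0], parts[1], frozenset(m for m in parts[2:] if m)
            if not members:
                raise ValueError(f"{path}:{lineno}: pathway {pid} has no members")
            if pid in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid}")
            pathways[pid] = (desc, members)
    if background is None:
        bg: frozenset = frozenset().union(*(m for _, m in pathways.values())) if pathways else frozenset()
    else:
        bg = frozenset(background)
    return PathwayDB(pathways=pathways, background=bg)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, members) in db.pathways.items():
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(query: set, db: PathwayDB, fdr_method: str = "bh") -> list[EnrichmentRow]:
    """Upper-tail hypergeometric ORA of ``query`` against every pathway.

    Rows are sorted by ascending p-value; ``found``/``total`` mirror the
    "entities found" / "entities total" columns of a Reactome-style
    report.
    """
    if not query:
        raise ValueError("empty query")
    q = frozenset(query)
    outside = q - db.background
    if outside:
        warnings.warn(f"dropping {len(outside)} query protein(s) outside the background")
        q = q & db.background
    if not q:
        raise ValueError("no query proteins inside the background")

    M, N = len(db.background), len(q)
    rows = []
    for pid, (name, members) in db.pathways.items():
        n = len(members)
        found = len(q & members)
        # P(X >= found) with X ~ Hypergeom(M, n, N)
        pvalue = float(hypergeom.sf(found - 1, M, n, N))
        rows.append(EnrichmentRow(pid, name, found, n, min(pvalue, 1.0), np.nan))
    if fdr_method == "bh":
        fdrs = bh_fdr([r.pvalue for r in rows])
    elif fdr_method == "bonferroni":
        fdrs = np.minimum(np.asarray([r.pvalue for r in rows]) * len(rows), 1.0)
    else:
        raise ValueError(f"unknown fdr_method {fdr_method!r}")
    for r, f in zip(rows, fdrs):
        r.fdr = float(f)
    rows.sort(key=lambda r: (r.pvalue, r.pathway_id))
    return rows


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in rows],
            "name": [r.pathway_name for r in rows],
            "found": [r.found for r in rows],
            "total": [r.total for r in rows],
            "pvalue": [r.pvalue for r in rows],
            "fdr": [r.fdr for r in rows],
        }
    )
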