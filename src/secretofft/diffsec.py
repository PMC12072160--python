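"""Secretome differential analysis.

Qualitative track: identification filter (>= k unique peptides), per-
condition identified sets, Venn partition into common / treatment-only /
control-only proteins.

Quantitative track: quantile normalization across samples, log2 fold
change of treatment over control condition means, UP/DOWN/NS calls at a
|log2 FC| threshold (default 1.5, strict inequality), and a clustergram
of row-wise Z-scored log abundances (z = (log x - row mean) / row SD)
with agglomerative clustering of rows and columns.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import AbundanceMatrix, DifferentialRecord, VennPartition, condition_of

__all__ = [
    "filter_min_unique_peptides",
    "identified_set",
    "venn_partition",
    "quantile_normalize",
    "log2_fold_change",
    "classify_differential",
    "zscore_autoscale",
    "clustergram",
    "Clustergram",
]


def filter_min_unique_peptides(matrix: AbundanceMatrix, k: int = 2) -> AbundanceMatrix:
    """Retain proteins identified by at least ``k`` unique peptides, order preserved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if matrix.unique_peptides is None:
        raise ValueError("matrix has no unique-peptide counts")
    keep = matrix.unique_peptides.reindex(matrix.proteins) >= k
    return AbundanceMatrix(
        values=matrix.values.loc[keep],
        unique_peptides=matrix.unique_peptides.loc[keep],
        names=None if matrix.names is None else matrix.names.reindex(matrix.proteins).loc[keep],
    )


def identified_set(matrix: AbundanceMatrix, condition: str) -> frozenset:
    """Proteins detected (non-missing) in at least one replicate of ``condition``."""
    cols = matrix.condition_samples(condition)
    present = matrix.values[cols].notna().any(axis=1)
    return frozenset(matrix.proteins[present])


def venn_partition(treatment: frozenset | set, control: frozenset | set) -> VennPartition:
    """Partition two identification lists into common and exclusive sets."""
    a, b = frozenset(treatment), frozenset(control)
    return VennPartition(common=a & b, treatment_only=a - b, control_only=b - a)


def quantile_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Quantile normalization across samples.

    The reference distribution is the mean of the per-sample sorted value
    vectors; every sample's observed values are replaced by the reference
    quantiles at their within-sample ranks, with tied values receiving
    the mean of the tied reference quantiles.  Missing values stay
    missing: a sample with n observed values uses the reference
    interpolated onto n equally spaced probability points, which reduces
    to the classical equal-length algorithm when nothing is missing.
    """
    X = matrix.values.to_numpy(float)
    n_rows, n_cols = X.shape
    if n_cols < 2:
        raise ValueError("need at least 2 samples")
    n_obs = (~np.isnan(X)).sum(axis=0)
    if np.any(n_obs == 0):
        bad = matrix.samples[n_obs == 0].tolist()
        raise ValueError(f"all-missing sample column(s): {bad}")

    grid = np.linspace(0.0, 1.0, n_rows) if n_rows > 1 else np.array([0.5])
    ref_cols = []
    for j in range(n_cols):
        obs = np.sort(X[~np.isnan(X[:, j]), j])
        if obs.size == 1:
            ref_cols.append(np.full(grid.size, obs[0]))
        else:
            ref_cols.append(np.interp(grid, np.linspace(0.0, 1.0, obs.size), obs))
    ref = np.mean(ref_cols, axis=0)

    out = np.full_like(X, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(X[:, j])
        col = X[mask, j]
        n = col.size
        if n == 1:
            ref_j = np.array([np.interp(0.5, grid, ref)])
        else:
            ref_j = np.interp(np.linspace(0.0, 1.0, n), grid, ref)
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref_j
        # ties: average the reference quantiles assigned to equal values
        s = pd.Series(assigned)
        assigned = s.groupby(pd.Series(col)).transform("mean").to_numpy()
        out[mask, j] = assigned

    result = matrix.copy()
    result.values = pd.DataFrame(out, index=matrix.proteins, columns=matrix.samples)
    return result


def log2_fold_change(
    matrix: AbundanceMatrix, treatment: str, control: str
) -> list[DifferentialRecord]:
    """Per-protein log2 of the ratio of condition means (treatment / control).

    Means are taken over the observed replicates of each condition.
    Proteins missing entirely in either condition belong to the
    qualitative (Venn) track and are excluded here; nonpositive means are
    excluded with a warning.
    """
    t_cols = matrix.condition_samples(treatment)
    c_cols = matrix.condition_samples(control)
    t_mean = matrix.values[t_cols].mean(axis=1, skipna=True)
    c_mean = matrix.values[c_cols].mean(axis=1, skipna=True)

    records: list[DifferentialRecord] = []
    for prot in matrix.proteins:
        tm, cm = t_mean[prot], c_mean[prot]
        if np.isnan(tm) or np.isnan(cm):
            continue
        if tm <= 0 or cm <= 0:
            warnings.warn(f"nonpositive condition mean for {prot}; excluded")
            continue
        name = None if matrix.names is None else matrix.names.get(prot)
        records.append(DifferentialRecord(protein=prot, log2fc=float(np.log2(tm / cm)), name=name))
    return records


def classify_differential(
    records: list[DifferentialRecord], threshold: float = 1.5
) -> list[DifferentialRecord]:
    """Call UP if log2fc > threshold, DOWN if log2fc < -threshold, else NS (strict)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = []
    for r in records:
        if r.log2fc > threshold:
            call = "UP"
        elif r.log2fc < -threshold:
            call = "DOWN"
        else:
            call = "NS"
        out.append(DifferentialRecord(protein=r.protein, log2fc=r.log2fc, call=call, name=r.name))
    return out


def differential_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    """Flatten differential records to a protein / log2fc / call table."""
    return pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "log2fc": [r.log2fc for r in records],
            "call": [r.call for r in records],
        }
    )


def zscore_autoscale(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Log-transform and row-autoscale proteins quantified in all samples.

    Each complete row x becomes (log x - mean) / SD.  The log base is
    immaterial (autoscaling cancels it); natural log is used.  Zero-SD
    rows are dropped with a warning; nonpositive values are an error.
    """
    complete = matrix.values.dropna(axis=0, how="any")
    bad = complete.index[(complete <= 0).any(axis=1)]
    if len(bad):
        raise ValueError(f"nonpositive abundance under log for protein(s): {list(bad[:5])}")
    logged = np.log(complete)
    sd = logged.std(axis=1, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} zero-variance protein row(s)")
    logged = logged.loc[~zero]
    z = logged.sub(logged.mean(axis=1), axis=0).div(logged.std(axis=1, ddof=0), axis=0)
    return z


@dataclass
class Clustergram:
    """Z-score matrix with agglomerative row/column trees and leaf orders."""

    zscores: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[int]
    col_order: list[int]

    def row_newick(self) -> str:
        return _linkage_to_newick(self.row_linkage, list(self.zscores.index))

    def col_newick(self) -> str:
        return _linkage_to_newick(self.col_linkage, list(self.zscores.columns))


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return build(tree, tree.dist) + ";"


def clustergram(
    zscores: pd.DataFrame,
    linkage: str = "average",
    metric: str = "euclidean",
) -> Clustergram:
    """Hierarchical clustering of the Z-score matrix along both axes."""
    if linkage not in ("average", "ward", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    if zscores.shape[0] < 2 or zscores.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    X = zscores.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("NaN in clustergram input")
    row_Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    col_Z = hierarchy.linkage(pdist(X.T, metric=metric), method=linkage)
    return Clustergram(
        zscores=zscores,
        row_linkage=row_Z,
        col_linkage=col_Z,
        row_order=hierarchy.leaves_list(row_Z).tolist(),
        col_order=hierarchy.leaves_list(col_Z).tolist(),
    )
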