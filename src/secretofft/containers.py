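"""Shared in-memory containers for the secretome and fiber-imaging tracks.

The quantitative secretome track revolves around :class:`AbundanceMatrix`
(proteins x samples, explicit missingness, condition labels per sample);
the qualitative track around :class:`VennPartition`; the fiber track
around :class:`FiberImage`.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Treatment conditions of the KGN stimulation experiment.
CONDITIONS = ("CTR", "FSH", "hCG", "FSH_hCG")


def condition_of(sample: str) -> str:
    """Infer the condition label from a ``<condition>_<replicate>`` sample id."""
    cond, _, rep = sample.rpartition("_")
    if not cond or not rep.isdigit():
        raise ValueError(f"sample id {sample!r} is not '<condition>_<replicate>'")
    return cond


@dataclass
class PeptideTable:
    """Peptide-level precursor areas.

    ``df`` has columns ``protein_id``, ``peptide_id`` and one column per
    sample; missing areas are NaN, never zero.  ``dropped`` (optional,
    simulator bookkeeping) is a boolean protein x condition frame marking
    proteins undetected in a whole condition.
    """

    df: pd.DataFrame
    dropped: pd.DataFrame | None = None

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("protein_id", "peptide_id")]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "PeptideTable":
        df = pd.read_csv(path, sep="\t")
        if "protein_id" not in df.columns or "peptide_id" not in df.columns:
            raise ValueError("peptide table needs protein_id and peptide_id columns")
        return cls(df=df)


@dataclass
class AbundanceMatrix:
    """Protein abundances (proteins x samples) with explicit missingness.

    values
        DataFrame indexed by protein accession, one column per sample id
        (``<condition>_<replicate>``); NaN marks not-detected.
    unique_peptides
        per-protein unique peptide count used by the identification filter.
    names
        optional accession -> human-readable protein name.
    """

    values: pd.DataFrame
    unique_peptides: pd.Series | None = None
    names: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        finite = np.isfinite(self.values.to_numpy(float))
        present = ~np.isnan(self.values.to_numpy(float))
        if not np.all(finite | ~present):
            raise ValueError("non-finite abundance values")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def conditions(self) -> pd.Series:
        return pd.Series({s: condition_of(s) for s in self.values.columns})

    def condition_samples(self, condition: str) -> list[str]:
        cols = [s for s in self.values.columns if condition_of(s) == condition]
        if not cols:
            raise KeyError(f"no samples for condition {condition!r}")
        return cols

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            values=self.values.copy(),
            unique_peptides=None if self.unique_peptides is None else self.unique_peptides.copy(),
            names=None if self.names is None else self.names.copy(),
        )

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "protein_id", out.index)
        if self.names is not None:
            out.insert(1, "name", self.names.reindex(self.values.index))
        if self.unique_peptides is not None:
            out.insert(1, "unique_peptides", self.unique_peptides.reindex(self.values.index))
        out.to_csv(path, sep="\t", index=False, na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t")
        if "protein_id" not in df.columns:
            raise ValueError("abundance table needs a protein_id column")
        df = df.set_index("protein_id")
        up = df.pop("unique_peptides").astype(int) if "unique_peptides" in df.columns else None
        names = df.pop("name") if "name" in df.columns else None
        return cls(values=df.astype(float), unique_peptides=up, names=names)


@dataclass(frozen=True)
class VennPartition:
    """Disjoint partition of two identification lists."""

    common: frozenset
    treatment_only: frozenset
    control_only: frozenset

    def __post_init__(self) -> None:
        assert self.common.isdisjoint(self.treatment_only)
        assert self.common.isdisjoint(self.control_only)
        assert self.treatment_only.isdisjoint(self.control_only)

    @property
    def union(self) -> frozenset:
        return self.common | self.treatment_only | self.control_only

    def to_dict(self) -> dict:
        return {
            "common": sorted(self.common),
            "treatment_only": sorted(self.treatment_only),
            "control_only": sorted(self.control_only),
        }


@dataclass
class DifferentialRecord:
    """A protein's log2 fold change and UP/DOWN/NS call."""

    protein: str
    log2fc: float
    call: str | None = None
    name: str | None = None


@dataclass
class FiberImage:
    """Grayscale fluorescence image of stained filaments (nonnegative, finite)."""

    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D grayscale")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.pixels.min() < 0:
            raise ValueError("image contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
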