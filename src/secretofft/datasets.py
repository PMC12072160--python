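"""Bundled reference tables.

The package ships the published differential-expression tables of the
KGN gonadotropin-stimulation secretome study (log2 fold change of each
treatment versus the untreated control) as plain TSV, so the
classification and enrichment stages can be exercised against real
printed values without any download.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .containers import DifferentialRecord

_FILES = {
    "FSH": "kgn_fsh_log2fc.tsv",
    "hCG": "kgn_hcg_log2fc.tsv",
    "FSH_hCG": "kgn_fsh_hcg_log2fc.tsv",
}

TREATMENTS = tuple(_FILES)


def load_differential_table(treatment: str) -> pd.DataFrame:
    """Published log2 fold changes (treatment vs CTR) as a DataFrame."""
    if treatment not in _FILES:
        raise KeyError(f"unknown treatment {treatment!r}; one of {TREATMENTS}")
    path = resources.files("secretofft.data") / _FILES[treatment]
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def load_differential_records(treatment: str) -> list[DifferentialRecord]:
    df = load_differential_table(treatment)
    return [
        DifferentialRecord(protein=row.protein, log2fc=float(row.log2fc), name=row.protein)
        for row in df.itertuples()
    ]
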