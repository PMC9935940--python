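"""Shared in-memory containers for counts and gene annotation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Columns every gene-annotation table must carry.
ANNOTATION_COLUMNS = ("chromosome", "exonic_length", "biotype", "is_ribo_or_mito")


@dataclass
class CountMatrix:
    """Genes x samples integer counts plus per-gene annotation.

    ``counts`` is a DataFrame indexed by gene id with one column per sample;
    ``annotation`` is indexed by the same gene ids and carries at least
    chromosome, exonic_length (bp), biotype and an is_ribo_or_mito flag.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("duplicate gene ids in count matrix")
        if (np.asarray(self.counts.to_numpy()) < 0).any():
            bad = self.counts.lt(0).any()
            col = bad[bad].index[0]
            row = self.counts.index[self.counts[col].lt(0)][0]
            raise ValueError(f"negative count at gene {row!r}, sample {col!r}")
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotation.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if not self.counts.index.equals(self.annotation.index):
            self.annotation = self.annotation.loc[self.counts.index]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        """Counts per million, per sample."""
        lib = self.library_sizes.astype(float)
        if (lib == 0).any():
            raise ValueError("zero library size")
        return self.counts.div(lib, axis=1) * 1e6

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.annotation.loc[genes])

    def is_chr21(self, chrom: str = "chr21") -> pd.Series:
        return self.annotation["chromosome"].eq(chrom)
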