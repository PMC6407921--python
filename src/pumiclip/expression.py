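"""Count-matrix normalization (CPM, FPKM) and between-genotype fold-changes.

Differential-expression modelling is deliberately out of scope: the
downstream cumulative-distribution analyses only need a per-gene
fold-change, so a pseudocounted ratio of mean CPM between genotypes is
used.  "Fragments" are deduplicated single-end reads here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """A genes x samples count matrix with its sample annotation.

    ``counts`` is indexed by gene_id with one column per sample;
    ``samples`` carries at least sample_id, genotype and replicate, one
    row per counts column, in column order.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series | None = None  # tx_length per gene, for FPKM

    def __post_init__(self) -> None:
        if list(self.samples["sample_id"]) != list(self.counts.columns):
            raise ValueError("sample sheet order must match counts columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def genotype_columns(self, genotype: str) -> list[str]:
        cols = list(self.samples.loc[self.samples["genotype"] == genotype, "sample_id"])
        if not cols:
            raise ValueError(f"unknown genotype label {genotype!r}")
        return cols


def filter_expressed(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep genes with at least one read in at least one sample."""
    keep = matrix.counts.max(axis=1) >= 1
    lengths = matrix.lengths[keep[keep].index] if matrix.lengths is not None else None
    return ExpressionMatrix(matrix.counts.loc[keep], matrix.samples, lengths)


def cpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts per million mapped reads, per sample."""
    totals = matrix.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-total sample column(s): {bad}")
    return matrix.counts * 1e6 / totals


def fpkm(matrix: ExpressionMatrix, lengths: Mapping[str, int] | pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if lengths is None:
        lengths = matrix.lengths
    if lengths is None:
        raise ValueError("fpkm requires per-gene transcript lengths")
    lengths = pd.Series(lengths)
    missing = matrix.counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing transcript length for gene(s): {list(missing[:5])}")
    lens = lengths.loc[matrix.counts.index].astype(float)
    if (lens <= 0).any():
        raise ValueError("transcript lengths must be positive")
    totals = matrix.counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-total sample column(s)")
    return matrix.counts.mul(1e9 / lens, axis=0) / totals


def mean_by_genotype(layer: pd.DataFrame, matrix: ExpressionMatrix, genotype: str) -> pd.Series:
    """Per-gene mean of a normalized layer over one genotype's replicates."""
    return layer[matrix.genotype_columns(genotype)].mean(axis=1)


def log2_fold_change(
    matrix: ExpressionMatrix,
    genotype_a: str,
    genotype_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean CPM in a + pc) / (mean CPM in b + pc))."""
    layer = cpm(matrix)
    mean_a = mean_by_genotype(layer, matrix, genotype_a)
    mean_b = mean_by_genotype(layer, matrix, genotype_b)
    return pd.Series(
        np.log2((mean_a + pseudocount) / (mean_b + pseudocount)),
        index=matrix.counts.index,
        name=f"log2fc_{genotype_a}_vs_{genotype_b}",
    )
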