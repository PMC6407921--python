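"""Shared genomic coordinate types and coverage computation.

All coordinates are 0-based, half-open ``[start, end)``, the native
convention of BED and bedGraph.  Coverage and every downstream counting
step are strand-specific: a read contributes only to features on the
same chromosome and strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

Strand = str  # "+" or "-"

_VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval.

    Attributes
    ----------
    chrom : str
        Chromosome / contig name (non-empty).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: Strand = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class ReadRecord:
    """An aligned read with its sample of origin and UMI tag."""

    interval: GenomicInterval
    sample_id: str
    umi: str

    def __post_init__(self) -> None:
        if not self.umi:
            raise ValueError(f"read in sample {self.sample_id!r} has an empty UMI")
        if set(self.umi) - set("ACGT"):
            raise ValueError(f"UMI {self.umi!r} contains non-ACGT characters")


@dataclass(frozen=True)
class GeneModel:
    """A single-exon gene with its transcript span, 3'UTR and sequence.

    ``sequence`` is the transcript in 5'->3' orientation (RNA or DNA
    alphabet; ``T`` is treated as ``U`` by the motif scanner).  For the
    synthetic single-exon genes used throughout, transcript coordinates
    map to genomic coordinates by a fixed offset (plus-strand genes) so
    ``tx_length == len(span)``.
    """

    gene_id: str
    span: GenomicInterval
    utr3: GenomicInterval
    tx_length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.utr3.chrom != self.span.chrom or self.utr3.strand != self.span.strand:
            raise ValueError(f"{self.gene_id}: 3'UTR must lie on the gene's chrom/strand")
        if self.utr3.start < self.span.start or self.utr3.end > self.span.end:
            raise ValueError(f"{self.gene_id}: 3'UTR must be contained in the span")
        if self.tx_length < len(self.utr3):
            raise ValueError(f"{self.gene_id}: tx_length shorter than 3'UTR")
        if self.sequence is not None and len(self.sequence) != self.tx_length:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != tx_length {self.tx_length}"
            )

    def tx_to_genomic(self, tx_pos: int) -> int:
        """Map a transcript position to its genomic start coordinate.

        Single-exon mapping: offset from span start on '+', mirrored on '-'.
        """
        if self.span.strand == "+":
            return self.span.start + tx_pos
        return self.span.end - tx_pos - 1


@dataclass
class CoverageTrack:
    """Per-base read coverage over a stated span of one chrom/strand."""

    chrom: str
    strand: Strand
    span_start: int
    values: np.ndarray = field(repr=False)

    @property
    def span_end(self) -> int:
        return self.span_start + len(self.values)

    def at(self, pos: int) -> int:
        if self.span_start <= pos < self.span_end:
            return int(self.values[pos - self.span_start])
        return 0


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chrom/strand)."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap_between(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Edge-to-edge gap in nt between two intervals on the same chrom/strand.

    0 when the intervals overlap or are adjacent; ``None`` when they are
    not comparable (different chrom or strand).
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def compute_coverage(
    reads: Iterable[ReadRecord],
    chrom: str,
    strand: Strand,
    span: Optional[tuple[int, int]] = None,
) -> CoverageTrack:
    """Per-nucleotide read coverage on one chromosome strand.

    Reads on other chromosomes or strands are ignored.  When ``span`` is
    omitted the track covers the minimal interval containing all
    selected reads (an empty all-zero track of length 0 if none).
    """
    starts = []
    ends = []
    for r in reads:
        iv = r.interval
        if iv.chrom == chrom and iv.strand == strand:
            starts.append(iv.start)
            ends.append(iv.end)
    if span is None:
        if not starts:
            return CoverageTrack(chrom, strand, 0, np.zeros(0, dtype=np.int64))
        span = (min(starts), max(ends))
    lo, hi = span
    n = max(0, hi - lo)
    diff = np.zeros(n + 1, dtype=np.int64)
    if starts:
        s = np.clip(np.asarray(starts, dtype=np.int64) - lo, 0, n)
        e = np.clip(np.asarray(ends, dtype=np.int64) - lo, 0, n)
        np.add.at(diff, s, 1)
        np.add.at(diff, e, -1)
    values = np.cumsum(diff[:-1])
    return CoverageTrack(chrom, strand, lo, values)
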