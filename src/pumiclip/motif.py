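"""PUMILIO response element (PRE) scanning and PRE-cluster proximity.

The perfect PRE is the octamer UGUANAUA; the relaxed consensus UGUANAUN
allows any final base.  A site is classified "perfect" when the final
base is A and "relaxed" otherwise, so the two classes are disjoint and
their union is the set of UGUANAUN matches.  Overlapping occurrences
each count once; T is treated as U so DNA-alphabet transcripts scan
identically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import GeneModel, GenomicInterval, gap_between
from .clusters import ClipCluster

PRE_LENGTH = 8

# lookahead so overlapping octamers are all reported; group 1 = final base
_PRE_RE = re.compile(r"(?=UGUA[ACGU]AU([ACGU]))")
_VALID_RE = re.compile(r"[^ACGU]")


@dataclass(frozen=True)
class PRESite:
    """One PRE occurrence on a transcript."""

    gene_id: str
    tx_position: int                  # 0-based octamer start in the transcript
    klass: str                        # "perfect" or "relaxed"
    genomic_position: Optional[int] = None  # octamer start on the genome


def scan_pre(sequence: str, gene_id: str = "") -> list[PRESite]:
    """All PRE octamers in a transcript, positions ascending.

    Accepts RNA or DNA alphabet (case-insensitive); raises on any other
    character, naming its position.
    """
    seq = sequence.upper().replace("T", "U")
    bad = _VALID_RE.search(seq)
    if bad is not None:
        raise ValueError(
            f"invalid character {bad.group()!r} at position {bad.start()}"
            + (f" in {gene_id}" if gene_id else "")
        )
    sites = []
    for m in _PRE_RE.finditer(seq):
        klass = "perfect" if m.group(1) == "A" else "relaxed"
        sites.append(PRESite(gene_id=gene_id, tx_position=m.start(), klass=klass))
    return sites


def scan_gene(gene: GeneModel) -> list[PRESite]:
    """Scan a gene's transcript and attach genomic octamer coordinates."""
    if gene.sequence is None:
        raise ValueError(f"{gene.gene_id}: no transcript sequence to scan")
    sites = scan_pre(gene.sequence, gene.gene_id)
    out = []
    for s in sites:
        if gene.span.strand == "+":
            gpos = gene.span.start + s.tx_position
        else:
            gpos = gene.span.end - s.tx_position - PRE_LENGTH
        out.append(PRESite(s.gene_id, s.tx_position, s.klass, genomic_position=gpos))
    return out


def site_interval(site: PRESite, gene: GeneModel) -> GenomicInterval:
    if site.genomic_position is None:
        raise ValueError(f"{site.gene_id}: site lacks a genomic position")
    return GenomicInterval(
        gene.span.chrom, site.genomic_position,
        site.genomic_position + PRE_LENGTH, gene.span.strand,
    )


def count_pres_near_clusters(
    gene: GeneModel,
    sites: Sequence[PRESite],
    clusters: Sequence[ClipCluster],
    window: int,
) -> int:
    """Number of PREs whose octamer lies within ``window`` nt of (or
    overlaps) any cluster interval; the gap is measured edge to edge and
    the boundary is inclusive."""
    if window < 0:
        raise ValueError("window must be >= 0")
    n = 0
    for s in sites:
        iv = site_interval(s, gene)
        for c in clusters:
            gap = gap_between(iv, c.interval)
            if gap is not None and gap <= window:
                n += 1
                break
    return n
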