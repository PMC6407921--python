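"""UMI-based PCR-duplicate removal and usable-read accounting.

Reads sharing (chrom, start, strand, UMI) are PCR duplicates of one
molecule; exactly one is retained.  The read end is deliberately not
part of the key — trimming can shorten otherwise identical molecules.
Reads surviving deduplication are the "usable reads" whose total is the
denominator of every depth normalization downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import ReadRecord


@dataclass
class SampleLibrary:
    """One sequencing library: IP or size-matched input of one replicate."""

    sample_id: str
    genotype: str          # "WT" or "KO"
    kind: str              # "IP" or "input"
    replicate: int
    reads: list[ReadRecord] = field(default_factory=list, repr=False)
    total_usable: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("IP", "input"):
            raise ValueError(f"{self.sample_id}: kind must be 'IP' or 'input'")
        if self.replicate < 1:
            raise ValueError(f"{self.sample_id}: replicate index must be >= 1")

    def dedup(self) -> "SampleLibrary":
        """Return self after in-place UMI deduplication and usable counting."""
        self.reads = dedup_umi(self.reads)
        self.total_usable = count_usable(self)
        return self


def dedup_umi(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Collapse PCR duplicates, keyed on (chrom, start, strand, UMI).

    For each key the retained read is the first under a deterministic
    sort (by end, then original input order), so output is identical
    across runs and platforms.  Output is sorted by coordinate.
    """
    best: dict[tuple, tuple] = {}
    for order, r in enumerate(reads):
        if not r.umi:
            raise ValueError(f"read #{order} in sample {r.sample_id!r} lacks a UMI")
        iv = r.interval
        key = (iv.chrom, iv.start, iv.strand, r.umi)
        rank = (iv.end, order)
        prev = best.get(key)
        if prev is None or rank < prev[0]:
            best[key] = (rank, r)
    kept = [r for _, r in best.values()]
    kept.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end,
                             r.interval.strand, r.umi))
    return kept


def count_usable(library: SampleLibrary) -> int:
    """Number of usable (deduplicated) reads in the library."""
    return len(library.reads)


def pair_libraries(libraries: Sequence[SampleLibrary]) -> dict[tuple[str, int], tuple[SampleLibrary, SampleLibrary]]:
    """Pair IP with its size-matched input per (genotype, replicate)."""
    by_key: dict[tuple[str, int, str], SampleLibrary] = {}
    for lib in libraries:
        k = (lib.genotype, lib.replicate, lib.kind)
        if k in by_key:
            raise ValueError(f"duplicate library for genotype={lib.genotype} "
                             f"replicate={lib.replicate} kind={lib.kind}")
        by_key[k] = lib
    pairs: dict[tuple[str, int], tuple[SampleLibrary, SampleLibrary]] = {}
    for (genotype, replicate, kind), lib in by_key.items():
        if kind != "IP":
            continue
        inp = by_key.get((genotype, replicate, "input"))
        if inp is None:
            raise ValueError(f"IP sample {lib.sample_id} has no matching input "
                             f"(genotype={genotype}, replicate={replicate})")
        pairs[(genotype, replicate)] = (lib, inp)
    return pairs
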