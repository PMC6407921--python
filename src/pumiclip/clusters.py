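"""Input-normalized eCLIP cluster calling.

The caller proceeds in four stages, each an independently testable
operation:

1. candidate bins — maximal runs of IP read coverage at or above a
   floor (default 3);
2. per-bin counting of IP and input reads, requiring at least half of a
   read's length inside the bin, and the input-normalized fold-change
   ``((ip+1)/ip_total) / ((input+1)/input_total)``; bins at or above the
   fold-change threshold (default 4) are per-replicate clusters;
3. a reproducibility filter keeping clusters detected (>= 1 bp overlap)
   in both biological replicates of either genotype;
4. merging of clusters that overlap by at least 30% of the shorter
   cluster's length, iterated to a fixed point with per-replicate
   counts recomputed over each merged interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .core import CoverageTrack, GenomicInterval, ReadRecord, compute_coverage, overlap_length
from .preprocess import SampleLibrary, pair_libraries

RepKey = tuple[str, int]  # (genotype, replicate)


@dataclass(frozen=True)
class PipelineParams:
    """Every threshold of the analysis, with its published default."""

    min_coverage: int = 3           # coverage floor for candidate bins
    read_bin_overlap_frac: float = 0.5   # fraction of a read inside the bin
    min_fold_change: float = 4.0    # normalized fold-change cutoff
    merge_frac: float = 0.3         # reciprocal-overlap fraction for merging
    pre_window: int = 100           # nt between a PRE and a cluster
    min_fpkm: float = 1.0           # expression floor for occupancy
    min_pres_cross_tissue: int = 2  # PREs near clusters for cross-tissue targets
    occupancy_increase_fold: float = 2.0  # KO/WT occupancy subset cutoff
    match_tolerance: float = 0.25   # non-target matching window half-width

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        for name in ("read_bin_overlap_frac", "merge_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0 < self.match_tolerance < 1):
            raise ValueError("match_tolerance must lie in (0, 1)")
        for name in ("min_fold_change", "min_fpkm", "occupancy_increase_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pre_window < 0 or self.min_pres_cross_tissue < 0:
            raise ValueError("window/count parameters must be non-negative")


@dataclass(frozen=True)
class CandidateBin:
    """A coverage bin with its IP/input read counts and fold-change."""

    interval: GenomicInterval
    ip_reads: int
    input_reads: int
    ip_total: int
    input_total: int
    nfc: float


@dataclass
class ClipCluster:
    """A reproducible, merged binding-site call.

    ``nfc``/``ip_reads``/``input_reads`` are per-replicate maps keyed by
    (genotype, replicate); ``supporting_genotype`` records in which
    genotype(s) the cluster passed the reproducibility filter.
    """

    interval: GenomicInterval
    nfc: dict[RepKey, float] = field(default_factory=dict)
    ip_reads: dict[RepKey, int] = field(default_factory=dict)
    input_reads: dict[RepKey, int] = field(default_factory=dict)
    supporting_genotype: str = "NA"  # "WT", "KO" or "both"

    @property
    def max_nfc(self) -> float:
        return max(self.nfc.values()) if self.nfc else float("nan")


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def call_candidate_bins(track: CoverageTrack, min_coverage: int) -> list[GenomicInterval]:
    """Maximal runs of positions with coverage >= ``min_coverage``."""
    mask = np.asarray(track.values) >= min_coverage
    if mask.size == 0 or not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [
        GenomicInterval(track.chrom, track.span_start + int(s),
                        track.span_start + int(e), track.strand)
        for s, e in zip(starts, ends)
    ]


class ReadIndex:
    """Start-sorted per-(chrom, strand) read index for fast bin counting."""

    def __init__(self, reads: Sequence[ReadRecord]):
        groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for r in reads:
            iv = r.interval
            groups.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
        self._idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, int]] = {}
        for key, pairs in groups.items():
            arr = np.asarray(sorted(pairs), dtype=np.int64)
            starts, ends = arr[:, 0], arr[:, 1]
            max_len = int((ends - starts).max())
            self._idx[key] = (starts, ends, max_len)

    def count_in_region(self, region: GenomicInterval, overlap_frac: float) -> int:
        entry = self._idx.get((region.chrom, region.strand))
        if entry is None:
            return 0
        starts, ends, max_len = entry
        lo = np.searchsorted(starts, region.start - max_len, side="left")
        hi = np.searchsorted(starts, region.end, side="left")
        if hi <= lo:
            return 0
        s, e = starts[lo:hi], ends[lo:hi]
        ov = np.minimum(e, region.end) - np.maximum(s, region.start)
        return int(np.count_nonzero(ov >= overlap_frac * (e - s)))

    def span(self, chrom: str, strand: str) -> Optional[tuple[int, int]]:
        entry = self._idx.get((chrom, strand))
        if entry is None:
            return None
        starts, ends, _ = entry
        return int(starts[0]), int(ends.max())

    def chrom_strands(self) -> list[tuple[str, str]]:
        return sorted(self._idx)


def count_reads_in_region(
    reads: Sequence[ReadRecord] | ReadIndex,
    region: GenomicInterval,
    overlap_frac: float,
) -> int:
    """Reads whose overlap with ``region`` is >= ``overlap_frac`` of the
    read's own length (boundary inclusive)."""
    if not (0 < overlap_frac <= 1):
        raise ValueError("overlap_frac must lie in (0, 1]")
    idx = reads if isinstance(reads, ReadIndex) else ReadIndex(reads)
    return idx.count_in_region(region, overlap_frac)


def normalized_fold_change(
    ip_reads: int, input_reads: int, ip_total: int, input_total: int
) -> float:
    """Input-normalized fold-change of a bin:
    ``((ip+1)/ip_total) / ((input+1)/input_total)``."""
    if ip_total <= 0 or input_total <= 0:
        raise ValueError("empty usable-read library")
    return ((ip_reads + 1) / ip_total) / ((input_reads + 1) / input_total)


def call_clusters_per_replicate(
    ip: SampleLibrary,
    inp: SampleLibrary,
    params: PipelineParams = PipelineParams(),
) -> list[CandidateBin]:
    """Candidate bins from IP coverage, retained at nfc >= threshold."""
    if ip.kind != "IP" or inp.kind != "input":
        raise ValueError("expected an (IP, input) pair in that order")
    if (ip.genotype, ip.replicate) != (inp.genotype, inp.replicate):
        raise ValueError(
            f"IP/input pairing mismatch: {ip.sample_id} vs {inp.sample_id}"
        )
    if ip.total_usable is None or inp.total_usable is None:
        raise ValueError("libraries must be deduplicated (total_usable set) first")
    ip_idx = ReadIndex(ip.reads)
    input_idx = ReadIndex(inp.reads)
    out: list[CandidateBin] = []
    for chrom, strand in ip_idx.chrom_strands():
        span = ip_idx.span(chrom, strand)
        track = compute_coverage(ip.reads, chrom, strand, span=span)
        for bin_iv in call_candidate_bins(track, params.min_coverage):
            ip_n = ip_idx.count_in_region(bin_iv, params.read_bin_overlap_frac)
            input_n = input_idx.count_in_region(bin_iv, params.read_bin_overlap_frac)
            nfc = normalized_fold_change(ip_n, input_n, ip.total_usable, inp.total_usable)
            if nfc >= params.min_fold_change:
                out.append(
                    CandidateBin(bin_iv, ip_n, input_n,
                                 ip.total_usable, inp.total_usable, nfc)
                )
    return out


def filter_reproducible(
    per_replicate: Mapping[RepKey, Sequence[CandidateBin]],
    params: PipelineParams = PipelineParams(),
) -> list[ClipCluster]:
    """Keep per-replicate clusters detected in both replicates of either
    genotype (>= 1 bp overlap on the same strand)."""
    genotypes = sorted({g for g, _ in per_replicate})
    multi = [g for g in genotypes
             if len({r for gg, r in per_replicate if gg == g}) >= 2]
    if not multi:
        raise ValueError("reproducibility filter needs >= 2 replicates "
                         "in at least one genotype")

    def overlaps_any(bin_: CandidateBin, others: Sequence[CandidateBin]) -> bool:
        return any(overlap_length(bin_.interval, o.interval) >= 1 for o in others)

    kept: list[tuple[RepKey, CandidateBin]] = []
    for g in multi:
        reps = sorted(r for gg, r in per_replicate if gg == g)
        for r in reps:
            others = [b for r2 in reps if r2 != r
                      for b in per_replicate[(g, r2)]]
            for b in per_replicate[(g, r)]:
                if overlaps_any(b, others):
                    kept.append(((g, r), b))

    kept_by_genotype: dict[str, list[CandidateBin]] = {}
    for (g, _), b in kept:
        kept_by_genotype.setdefault(g, []).append(b)

    clusters: list[ClipCluster] = []
    for (g, r), b in kept:
        support = g
        for g2, bins2 in kept_by_genotype.items():
            if g2 != g and overlaps_any(b, bins2):
                support = "both"
        clusters.append(
            ClipCluster(
                interval=b.interval,
                nfc={(g, r): b.nfc},
                ip_reads={(g, r): b.ip_reads},
                input_reads={(g, r): b.input_reads},
                supporting_genotype=support,
            )
        )
    return clusters


Recount = Callable[[GenomicInterval], tuple[dict, dict, dict]]


def merge_clusters(
    clusters: Sequence[ClipCluster],
    merge_frac: float,
    recount: Optional[Recount] = None,
) -> list[ClipCluster]:
    """Merge clusters overlapping by >= ``merge_frac`` of the shorter
    cluster's length, iterating to a fixed point.

    The leftmost qualifying pair (in coordinate-sorted order) is always
    merged first, making the fixed point deterministic.  When a
    ``recount`` callback is given, per-replicate read counts and
    fold-changes of each merged interval are recomputed from the
    libraries; otherwise counts from the constituent clusters are
    combined conservatively (max per replicate).
    """
    def sort_key(c: ClipCluster):
        iv = c.interval
        return (iv.chrom, iv.strand, iv.start, iv.end)

    def qualifies(a: ClipCluster, b: ClipCluster) -> bool:
        ov = overlap_length(a.interval, b.interval)
        shorter = min(len(a.interval), len(b.interval))
        return ov >= merge_frac * shorter

    def combine(a: ClipCluster, b: ClipCluster) -> ClipCluster:
        iv = GenomicInterval(
            a.interval.chrom,
            min(a.interval.start, b.interval.start),
            max(a.interval.end, b.interval.end),
            a.interval.strand,
        )
        if a.supporting_genotype == b.supporting_genotype:
            support = a.supporting_genotype
        else:
            support = "both"
        if recount is not None:
            nfc, ip_map, input_map = recount(iv)
        else:
            nfc = dict(a.nfc)
            ip_map = dict(a.ip_reads)
            input_map = dict(a.input_reads)
            for k in b.nfc:
                nfc[k] = max(nfc.get(k, 0.0), b.nfc[k])
                ip_map[k] = max(ip_map.get(k, 0), b.ip_reads[k])
                input_map[k] = max(input_map.get(k, 0), b.input_reads[k])
        return ClipCluster(iv, nfc, ip_map, input_map, support)

    work = sorted((replace_counts(c, recount) for c in clusters), key=sort_key)
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(work) and not changed:
            a = work[i]
            j = i + 1
            while j < len(work):
                b = work[j]
                if (b.interval.chrom, b.interval.strand) != (a.interval.chrom, a.interval.strand):
                    break
                if b.interval.start >= a.interval.end:
                    break
                if qualifies(a, b):
                    merged = combine(a, b)
                    del work[j]
                    del work[i]
                    work.append(merged)
                    work.sort(key=sort_key)
                    changed = True
                    break
                j += 1
            i += 1
    return work


def replace_counts(c: ClipCluster, recount: Optional[Recount]) -> ClipCluster:
    """Refresh a cluster's per-replicate maps from the libraries."""
    if recount is None:
        return ClipCluster(c.interval, dict(c.nfc), dict(c.ip_reads),
                           dict(c.input_reads), c.supporting_genotype)
    nfc, ip_map, input_map = recount(c.interval)
    return ClipCluster(c.interval, nfc, ip_map, input_map, c.supporting_genotype)


# ---------------------------------------------------------------------------
# End-to-end caller
# ---------------------------------------------------------------------------

def make_recount(
    pairs: Mapping[RepKey, tuple[SampleLibrary, SampleLibrary]],
    params: PipelineParams,
) -> Recount:
    """Build a recount callback over all IP/input pairs (indexes cached)."""
    indexes = {
        key: (ReadIndex(ip.reads), ReadIndex(inp.reads),
              ip.total_usable, inp.total_usable)
        for key, (ip, inp) in pairs.items()
    }

    def recount(iv: GenomicInterval):
        nfc: dict[RepKey, float] = {}
        ip_map: dict[RepKey, int] = {}
        input_map: dict[RepKey, int] = {}
        for key in sorted(indexes):
            ip_idx, input_idx, ip_total, input_total = indexes[key]
            ip_n = ip_idx.count_in_region(iv, params.read_bin_overlap_frac)
            input_n = input_idx.count_in_region(iv, params.read_bin_overlap_frac)
            ip_map[key] = ip_n
            input_map[key] = input_n
            nfc[key] = normalized_fold_change(ip_n, input_n, ip_total, input_total)
        return nfc, ip_map, input_map

    return recount


def call_clusters(
    libraries: Sequence[SampleLibrary],
    params: PipelineParams = PipelineParams(),
) -> list[ClipCluster]:
    """Full caller: per-replicate bins -> reproducibility -> merging."""
    pairs = pair_libraries(libraries)
    per_rep = {
        key: call_clusters_per_replicate(ip, inp, params)
        for key, (ip, inp) in sorted(pairs.items())
    }
    reproducible = filter_reproducible(per_rep, params)
    return merge_clusters(reproducible, params.merge_frac,
                          recount=make_recount(pairs, params))
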