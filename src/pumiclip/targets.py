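"""Target definition, occupancy, matched controls and CDF statistics.

A gene with one or more CLIP clusters overlapping its 3'UTR is a
target.  Per-gene CLIP signal is the depth-weighted sum of reads in
those clusters (reads per million usable reads, summed over clusters
and replicates); occupancy divides the replicate-mean of that signal by
the gene's mean FPKM in the same genotype, and is left undefined below
an expression floor.  Matched non-targets resemble the target set in
mean log expression and mean 3'UTR length; distribution shifts are
scored with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import ClipCluster, PipelineParams, ReadIndex, RepKey
from .core import GeneModel, overlap_length
from .preprocess import SampleLibrary


@dataclass
class TargetGene:
    """A gene with 3'UTR CLIP clusters and its per-genotype quantities."""

    gene_id: str
    clusters: list[ClipCluster] = field(default_factory=list, repr=False)
    total_clip_reads: dict[str, float] = field(default_factory=dict)  # genotype -> RPM
    occupancy: dict[str, Optional[float]] = field(default_factory=dict)
    pre_count_near_clusters: Optional[int] = None
    occupancy_ratio: Optional[float] = None  # KO / WT


@dataclass
class CdfComparison:
    """Two-sample KS comparison with exported empirical CDFs."""

    target_values: np.ndarray
    control_values: np.ndarray
    ks_statistic: float
    p_value: float

    def ecdf(self, which: str = "target") -> tuple[np.ndarray, np.ndarray]:
        v = np.sort(self.target_values if which == "target" else self.control_values)
        return v, np.arange(1, len(v) + 1) / len(v)


# ---------------------------------------------------------------------------
# Cluster -> gene assignment and per-gene quantification
# ---------------------------------------------------------------------------

def assign_clusters_to_utr3(
    clusters: Sequence[ClipCluster],
    genes: Sequence[GeneModel],
) -> dict[str, list[ClipCluster]]:
    """Gene -> clusters overlapping its 3'UTR (>= 1 bp, same strand).

    A cluster overlapping two genes' UTRs is assigned to both.
    """
    groups: dict[tuple[str, str], list[tuple[int, int, ClipCluster]]] = {}
    for c in clusters:
        iv = c.interval
        groups.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end, c))
    index = {}
    for key, items in groups.items():
        items.sort(key=lambda t: (t[0], t[1]))
        starts = np.array([s for s, _, _ in items])
        max_len = max(e - s for s, e, _ in items)
        index[key] = (starts, items, max_len)

    out: dict[str, list[ClipCluster]] = {}
    for g in genes:
        entry = index.get((g.utr3.chrom, g.utr3.strand))
        if entry is None:
            continue
        starts, items, max_len = entry
        lo = int(np.searchsorted(starts, g.utr3.start - max_len, side="left"))
        hi = int(np.searchsorted(starts, g.utr3.end, side="left"))
        mine = [c for s, e, c in items[lo:hi]
                if overlap_length(c.interval, g.utr3) >= 1]
        if mine:
            out[g.gene_id] = mine
    return out


class ClipQuantifier:
    """Caches per-replicate IP read indexes for repeated per-gene sums."""

    def __init__(self, libraries: Sequence[SampleLibrary], params: PipelineParams = PipelineParams()):
        self.params = params
        self.ip: dict[RepKey, tuple[ReadIndex, int]] = {}
        for lib in libraries:
            if lib.kind != "IP":
                continue
            if lib.total_usable is None:
                raise ValueError(f"{lib.sample_id}: dedup before quantification")
            self.ip[(lib.genotype, lib.replicate)] = (ReadIndex(lib.reads), lib.total_usable)

    def replicates(self, genotype: str) -> list[RepKey]:
        keys = sorted(k for k in self.ip if k[0] == genotype)
        if not keys:
            raise ValueError(f"no IP replicate for genotype {genotype!r}")
        return keys

    def rpm_in_clusters(self, clusters: Sequence[ClipCluster], genotype: str) -> float:
        """Depth-weighted read sum: reads-per-million per replicate, summed
        over clusters and replicates."""
        total = 0.0
        for key in self.replicates(genotype):
            idx, usable = self.ip[key]
            for c in clusters:
                n = idx.count_in_region(c.interval, self.params.read_bin_overlap_frac)
                total += n * 1e6 / usable
        return total

    def raw_reads_in_clusters(self, clusters: Sequence[ClipCluster], genotype: str) -> int:
        return sum(
            self.ip[key][0].count_in_region(c.interval, self.params.read_bin_overlap_frac)
            for key in self.replicates(genotype)
            for c in clusters
        )


def clip_reads_per_gene(
    clusters: Sequence[ClipCluster],
    quantifier: ClipQuantifier,
    genotype: str,
) -> float:
    """Total CLIP signal of one gene's 3'UTR clusters, in RPM units."""
    if not clusters:
        return 0.0
    return quantifier.rpm_in_clusters(clusters, genotype)


def occupancy(
    clusters: Sequence[ClipCluster],
    quantifier: ClipQuantifier,
    genotype: str,
    mean_fpkm: float,
    min_fpkm: float = 1.0,
) -> Optional[float]:
    """Replicate-mean cluster RPM divided by mean FPKM; ``None`` (gene
    excluded) when expression is below the floor."""
    if mean_fpkm < min_fpkm:
        return None
    n_rep = len(quantifier.replicates(genotype))
    rpm = quantifier.rpm_in_clusters(clusters, genotype)
    return (rpm / n_rep) / mean_fpkm


def build_targets(
    clusters: Sequence[ClipCluster],
    genes: Sequence[GeneModel],
    libraries: Sequence[SampleLibrary],
    fpkm_by_genotype: Mapping[str, pd.Series],
    params: PipelineParams = PipelineParams(),
    genotypes: Sequence[str] = ("WT", "KO"),
) -> list[TargetGene]:
    """Assemble the target table from merged clusters and expression."""
    by_gene = assign_clusters_to_utr3(clusters, genes)
    quant = ClipQuantifier(libraries, params)
    targets = []
    for gid in sorted(by_gene):
        t = TargetGene(gene_id=gid, clusters=by_gene[gid])
        for g in genotypes:
            t.total_clip_reads[g] = clip_reads_per_gene(t.clusters, quant, g)
            fpkm_g = fpkm_by_genotype[g].get(gid, 0.0)
            t.occupancy[g] = occupancy(t.clusters, quant, g, float(fpkm_g), params.min_fpkm)
        occ_wt, occ_ko = t.occupancy.get("WT"), t.occupancy.get("KO")
        if occ_wt is not None and occ_ko is not None and occ_wt > 0:
            t.occupancy_ratio = occ_ko / occ_wt
        targets.append(t)
    return targets


def rank_targets(
    targets: Sequence[TargetGene],
    genotype: str = "WT",
) -> tuple[list[TargetGene], dict]:
    """Targets sorted by total CLIP signal, with a super-target report.

    The report gives the ratio of the top target's signal to the 95th
    percentile of the remaining targets' signals.
    """
    if len(targets) < 2:
        raise ValueError("ranking needs at least two targets")
    ordered = sorted(
        targets, key=lambda t: (-t.total_clip_reads.get(genotype, 0.0), t.gene_id)
    )
    top = ordered[0]
    rest = np.array([t.total_clip_reads.get(genotype, 0.0) for t in ordered[1:]])
    p95 = float(np.percentile(rest, 95))
    ratio = float("inf") if p95 == 0 else top.total_clip_reads[genotype] / p95
    report = {
        "top_gene": top.gene_id,
        "top_signal": top.total_clip_reads[genotype],
        "p95_of_rest": p95,
        "ratio_top_to_p95": ratio,
        "n_targets": len(targets),
    }
    return ordered, report


# ---------------------------------------------------------------------------
# Matched non-targets and CDF statistics
# ---------------------------------------------------------------------------

def match_nontargets(
    target_ids: Sequence[str],
    expression: pd.Series,
    utr_lengths: pd.Series,
    tolerance: float = 0.25,
) -> list[str]:
    """Non-target genes matched to the target set.

    Keeps non-targets whose log10 expression lies within ``tolerance``
    (fractionally) of the target set's mean log10 expression and whose
    3'UTR length lies within ``tolerance`` of the targets' mean UTR
    length; both boundaries inclusive.
    """
    if not (0 < tolerance < 1):
        raise ValueError("tolerance must lie in (0, 1)")
    target_ids = list(target_ids)
    if not target_ids:
        raise ValueError("matching requires a non-empty target set")
    expr_t = expression.loc[target_ids]
    if (expr_t <= 0).any():
        bad = expr_t.index[expr_t <= 0][:5].tolist()
        raise ValueError(f"target expression must be positive, offenders: {bad}")
    mu = float(np.log10(expr_t).mean())
    if mu == 0:
        raise ValueError(
            "mean log10 target expression is 0: a fractional window around 0 "
            "is empty; rescale expression (e.g. to a depth-normalized unit "
            "with mean log10 != 0) before matching"
        )
    lo_e, hi_e = sorted(((1 - tolerance) * mu, (1 + tolerance) * mu))
    lbar = float(utr_lengths.loc[target_ids].mean())
    lo_u, hi_u = (1 - tolerance) * lbar, (1 + tolerance) * lbar

    nontargets = expression.index.difference(target_ids)
    with np.errstate(divide="ignore"):
        log_e = np.log10(expression.loc[nontargets].astype(float))
    ok_e = (log_e >= lo_e) & (log_e <= hi_e)
    ul = utr_lengths.loc[nontargets].astype(float)
    ok_u = (ul >= lo_u) & (ul <= hi_u)
    return sorted(nontargets[(ok_e & ok_u).to_numpy()])


def cdf_compare(values_a, values_b, mode: str = "auto") -> CdfComparison:
    """Two-sample Kolmogorov-Smirnov comparison (two-sided).

    ``mode`` follows scipy: "auto" uses exact p-values for small samples
    and the asymptotic distribution otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method=mode)
    return CdfComparison(a, b, float(res.statistic), float(res.pvalue))


def select_occupancy_increased(
    targets: Sequence[TargetGene],
    min_ratio: float = 2.0,
) -> list[TargetGene]:
    """Targets whose KO/WT occupancy ratio is >= ``min_ratio`` (inclusive);
    targets without a defined ratio are dropped."""
    return [t for t in targets
            if t.occupancy_ratio is not None and t.occupancy_ratio >= min_ratio]


def cross_tissue_targets(
    targets: Sequence[TargetGene],
    second_tissue_fpkm: pd.Series,
    params: PipelineParams = PipelineParams(),
) -> list[TargetGene]:
    """Targets with >= ``min_pres_cross_tissue`` PREs near their 3'UTR
    clusters and expression >= ``min_fpkm`` in a second tissue."""
    out = []
    for t in targets:
        if t.pre_count_near_clusters is None:
            raise ValueError(f"{t.gene_id}: PRE annotation missing "
                             "(run the motif annotation first)")
        fpkm2 = float(second_tissue_fpkm.get(t.gene_id, 0.0))
        if (t.pre_count_near_clusters >= params.min_pres_cross_tissue
                and fpkm2 >= params.min_fpkm):
            out.append(t)
    return out


def targets_frame(targets: Sequence[TargetGene], genotypes=("WT", "KO")) -> pd.DataFrame:
    """Flat per-target table for TSV export."""
    rows = []
    for t in targets:
        row = {"gene_id": t.gene_id, "n_clusters": len(t.clusters)}
        for g in genotypes:
            row[f"clip_rpm_{g}"] = t.total_clip_reads.get(g)
            row[f"occupancy_{g}"] = t.occupancy.get(g)
        row["occupancy_ratio"] = t.occupancy_ratio
        row["pre_count_near_clusters"] = t.pre_count_near_clusters
        rows.append(row)
    return pd.DataFrame(rows)
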