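"""Synthetic eCLIP + RNA-seq experiment generator with ground truth.

The generator emulates the structure of the study system: two genotypes
(``WT`` and ``KO``, i.e. wild-type and lncRNA-knockout) with two CLIP
replicates each, every IP paired with a size-matched input; a subset of
genes carrying planted PUMILIO response elements (PREs) in their 3'UTRs
at which IP reads pile up; optionally one noncoding "super-target" gene
(a synthetic *Norad* analog with 11 perfect and 3 relaxed-only PREs)
drawing vastly more CLIP signal than any mRNA; and RNA-seq counts in
which target genes are modestly repressed in the knockout.

Generative model
----------------
* Genes are single-exon, non-overlapping, all on the plus strand of one
  synthetic chromosome, so transcript positions map to genomic positions
  by a fixed offset.
* Expression is log-uniform over [1, 1000] FPKM-equivalents.
* Input reads fall uniformly within transcripts, genes weighted by
  expression x length.
* IP reads are a mixture of an input-like background plus a site
  component: each planted PRE receives weight
  ``(ip_site_enrichment - 1) x site_reference_expression x tx_length``
  (x ``ko_occupancy_multiplier`` in the knockout), shared equally among
  the gene's sites, and a site read is placed so the octamer is
  uniformly positioned within the read.  Site strength is independent of
  the host gene's abundance, modelling high-affinity sites that saturate
  the immunoprecipitation.
* RNA-seq counts are negative binomial with variance ``mu + phi mu^2``;
  target means in KO are scaled by ``1 - repression_fraction``.
* One global seed; each sample's RNG is derived from the seed plus a
  stable hash of its label, so any sample is reproducible in isolation.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, ReadRecord
from .preprocess import SampleLibrary

CHROM = "chrS"
GENOTYPES = ("WT", "KO")
SUPER_TARGET_ID = "synNorad"
SUPER_TARGET_PERFECT = 11
SUPER_TARGET_RELAXED = 3
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    seed: int = 0
    n_genes: int = 100
    tx_length: int = 6000
    utr3_length: int = 1000
    frac_targets: float = 0.3
    pres_per_target: int = 2
    ip_site_enrichment: float = 8.0     # WT fold-enrichment of a planted site
    ko_occupancy_multiplier: float = 2.0  # site-weight multiplier in KO
    repression_fraction: float = 0.15   # KO target-expression decrease
    reads_per_ip_sample: int = 2000
    reads_per_input_sample: int = 2000
    rnaseq_depth: int = 5_000_000
    rnaseq_replicates: int = 3
    nb_dispersion: float = 0.1
    super_target: bool = False
    super_target_fold: float = 2000.0   # x median mRNA-target site weight
    super_target_length: int = 5200
    read_length: int = 35
    umi_length: int = 10
    duplicate_fraction: float = 0.1     # PCR-duplicate fraction of emitted reads
    site_reference_expression: float = 30.0  # abundance-equivalent of one
    # enrichment-fold of site binding (see docs/methods.md)
    site_spacing: int = 40              # octamer-start gap between paired PREs
    gene_gap: int = 500                 # intergenic spacing on the toy genome

    def __post_init__(self) -> None:
        positive = ("n_genes", "tx_length", "utr3_length", "pres_per_target",
                    "reads_per_ip_sample", "reads_per_input_sample",
                    "rnaseq_depth", "rnaseq_replicates", "read_length",
                    "umi_length", "nb_dispersion")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.frac_targets < 1):
            raise ValueError("frac_targets must lie in [0, 1)")
        if not (0 <= self.repression_fraction < 1):
            raise ValueError("repression_fraction must lie in [0, 1)")
        if not (0 <= self.duplicate_fraction < 1):
            raise ValueError("duplicate_fraction must lie in [0, 1)")
        if self.ip_site_enrichment < 1 or self.ko_occupancy_multiplier < 1:
            raise ValueError("enrichment parameters must be >= 1")
        if self.utr3_length >= self.tx_length:
            raise ValueError("utr3_length must be smaller than tx_length")
        if self.read_length >= self.utr3_length:
            raise ValueError("read_length must be smaller than utr3_length")
        block = (self.pres_per_target - 1) * self.site_spacing + 8
        if block + self.read_length + 10 > self.utr3_length:
            raise ValueError(
                "geometry infeasible: planted PREs and read margin do not "
                f"fit the 3'UTR ({block + self.read_length + 10} nt needed, "
                f"{self.utr3_length} nt available)"
            )


@dataclass
class GroundTruth:
    """Oracle record of what was planted, for parameter-recovery tests."""

    target_gene_ids: list[str]
    pre_positions: dict[str, list[int]]        # gene_id -> octamer tx starts
    expression: dict[str, dict[str, float]]    # genotype -> gene_id -> level
    site_weight: dict[str, dict[str, float]]   # genotype -> gene_id -> IP site weight
    expected_occupancy: dict[str, dict[str, float]]  # genotype -> gene_id -> value
    super_target_id: str | None = None


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-sample generator: seed + stable label hash."""
    tag = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


# ---------------------------------------------------------------------------
# Gene set
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


_HEPTAMER_RE = re.compile(b"(?=TGTA[ACGT]AT)")


def _plant_site(seq: np.ndarray, pos: int, rng: np.random.Generator,
                perfect: bool) -> None:
    middle = _BASES[rng.integers(0, 4)]
    octamer = b"TGTA" + middle.tobytes() + b"AT"
    last = b"A" if perfect else _BASES[rng.integers(1, 4)].tobytes()  # C/G/T
    seq[pos : pos + 8] = np.frombuffer(octamer + last, dtype="S1")


def _reject_spurious_pres(rng: np.random.Generator, seq: np.ndarray,
                          planted_starts: list[int]) -> np.ndarray:
    """Redraw bases until the only UGUANAU heptamers left start exactly at
    planted octamer positions.  Redrawing never touches planted octamer
    bases, so planted sites survive with their class intact."""
    allowed = set(planted_starts)
    octamer_bases = {p + k for p in planted_starts for k in range(8)}
    for _ in range(200):
        text = seq.tobytes()
        hits = [m.start() for m in _HEPTAMER_RE.finditer(text)
                if m.start() not in allowed]
        if not hits:
            return seq
        for h in hits:
            free = [q for q in range(h, h + 7) if q not in octamer_bases]
            for q in free:
                seq[q] = _random_sequence(rng, 1)[0]
    raise RuntimeError("rejection sampling failed to converge")


def build_gene_set(config: SynthConfig) -> tuple[list[GeneModel], GroundTruth]:
    """Toy genome: non-overlapping single-exon genes with planted PREs."""
    rng = rng_for(config.seed, "gene_set")
    n = config.n_genes
    width = len(str(max(n, 1)))
    gene_ids = [f"gene{i:0{width}d}" for i in range(n)]

    n_targets = int(round(config.frac_targets * n))
    target_idx = np.sort(rng.choice(n, size=n_targets, replace=False))
    target_ids = [gene_ids[i] for i in target_idx]

    expr_wt = 10.0 ** rng.uniform(0.0, 3.0, size=n)

    stride = config.tx_length + config.gene_gap
    genes: list[GeneModel] = []
    pre_positions: dict[str, list[int]] = {}
    utr_start_tx = config.tx_length - config.utr3_length

    block = (config.pres_per_target - 1) * config.site_spacing + 8
    lo = utr_start_tx
    hi = config.tx_length - config.read_length - block  # inclusive upper bound
    for i, gid in enumerate(gene_ids):
        seq = _random_sequence(rng, config.tx_length)
        sites: list[int] = []
        if i in target_idx:
            first = int(rng.integers(lo, hi + 1))
            sites = [first + k * config.site_spacing for k in range(config.pres_per_target)]
            for p in sites:
                _plant_site(seq, p, rng, perfect=True)
        seq = _reject_spurious_pres(rng, seq, sites)
        start = i * stride
        span = GenomicInterval(CHROM, start, start + config.tx_length, "+")
        utr3 = GenomicInterval(CHROM, start + utr_start_tx, start + config.tx_length, "+")
        genes.append(GeneModel(gid, span, utr3, config.tx_length, seq.tobytes().decode()))
        pre_positions[gid] = sites

    super_id = None
    if config.super_target:
        super_id = SUPER_TARGET_ID
        L = config.super_target_length
        n_sites = SUPER_TARGET_PERFECT + SUPER_TARGET_RELAXED
        margin = config.read_length + 10
        positions = np.linspace(margin, L - margin - 8, n_sites).astype(int).tolist()
        seq = _random_sequence(rng, L)
        relaxed_at = set(positions[3::5][:SUPER_TARGET_RELAXED])  # 3 spread-out sites
        for p in positions:
            _plant_site(seq, p, rng, perfect=p not in relaxed_at)
        seq = _reject_spurious_pres(rng, seq, positions)
        start = n * stride
        span = GenomicInterval(CHROM, start, start + L, "+")
        # noncoding: the whole transcript is treated as its 3'UTR
        genes.append(GeneModel(super_id, span, span, L, seq.tobytes().decode()))
        pre_positions[super_id] = positions

    # --- expression and IP site weights per genotype -----------------------
    expression = {g: {} for g in GENOTYPES}
    site_weight = {g: {} for g in GENOTYPES}
    target_set = set(target_ids)
    for i, gid in enumerate(gene_ids):
        wt = float(expr_wt[i])
        ko = wt * (1.0 - config.repression_fraction) if gid in target_set else wt
        expression["WT"][gid] = wt
        expression["KO"][gid] = ko
    if super_id is not None:
        expression["WT"][super_id] = 500.0
        expression["KO"][super_id] = 500.0

    base_site = (config.ip_site_enrichment - 1.0) * \
        config.site_reference_expression * config.tx_length
    for gid in gene_ids:
        w = base_site if gid in target_set else 0.0
        site_weight["WT"][gid] = w
        site_weight["KO"][gid] = w * config.ko_occupancy_multiplier
    if super_id is not None:
        s = config.super_target_fold * base_site
        site_weight["WT"][super_id] = s
        site_weight["KO"][super_id] = s  # lncRNA binding is not boosted in KO

    expected_occupancy = {g: {} for g in GENOTYPES}
    for g in GENOTYPES:
        total = sum(
            expression[g][gm.gene_id] * gm.tx_length + site_weight[g][gm.gene_id]
            for gm in genes
        )
        for gm in genes:
            gid = gm.gene_id
            if site_weight[g][gid] > 0:
                expected_occupancy[g][gid] = (
                    site_weight[g][gid] / total / expression[g][gid]
                )

    truth = GroundTruth(
        target_gene_ids=target_ids,
        pre_positions=pre_positions,
        expression=expression,
        site_weight=site_weight,
        expected_occupancy=expected_occupancy,
        super_target_id=super_id,
    )
    return genes, truth


# ---------------------------------------------------------------------------
# CLIP read simulation
# ---------------------------------------------------------------------------

def _umi_strings(rng: np.random.Generator, n: int, length: int) -> list[str]:
    arr = _BASES[rng.integers(0, 4, size=(n, length))]
    return [row.tobytes().decode() for row in arr]


def simulate_clip_sample(
    genes: list[GeneModel],
    truth: GroundTruth,
    config: SynthConfig,
    genotype: str,
    kind: str,
    replicate: int,
) -> list[ReadRecord]:
    """One CLIP library (IP or size-matched input) as aligned reads."""
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}")
    if kind not in ("IP", "input"):
        raise ValueError("kind must be 'IP' or 'input'")
    sample_id = f"{genotype}_{kind}_rep{replicate}"
    rng = rng_for(config.seed, sample_id)
    rl = config.read_length

    # mixture components: one background per gene (+ one per planted site
    # for IP libraries)
    comp_gene: list[int] = []
    comp_site: list[int] = []      # octamer tx position, -1 for background
    weights: list[float] = []
    for gi, gm in enumerate(genes):
        expr = truth.expression[genotype][gm.gene_id]
        comp_gene.append(gi)
        comp_site.append(-1)
        weights.append(expr * gm.tx_length)
        if kind == "IP":
            sw = truth.site_weight[genotype][gm.gene_id]
            sites = truth.pre_positions.get(gm.gene_id, [])
            if sw > 0 and sites:
                for p in sites:
                    comp_gene.append(gi)
                    comp_site.append(p)
                    weights.append(sw / len(sites))

    w = np.asarray(weights, dtype=float)
    w /= w.sum()
    n_reads = config.reads_per_ip_sample if kind == "IP" else config.reads_per_input_sample
    n_unique = max(1, int(round(n_reads * (1.0 - config.duplicate_fraction))))
    counts = rng.multinomial(n_unique, w)

    starts = np.empty(n_unique, dtype=np.int64)
    pos = 0
    for ci in np.flatnonzero(counts):
        k = int(counts[ci])
        gm = genes[comp_gene[ci]]
        if comp_site[ci] < 0:
            s = gm.span.start + rng.integers(0, gm.tx_length - rl + 1, size=k)
        else:
            site_g = gm.span.start + comp_site[ci]
            offset = rng.integers(0, rl - 8 + 1, size=k)
            s = np.clip(site_g - offset, gm.span.start, gm.span.end - rl)
        starts[pos : pos + k] = s
        pos += k

    umis = _umi_strings(rng, n_unique, config.umi_length)

    n_dup = n_reads - n_unique
    dup_idx = rng.integers(0, n_unique, size=n_dup) if n_dup else np.array([], dtype=int)

    reads: list[ReadRecord] = []
    for i in range(n_unique):
        iv = GenomicInterval(CHROM, int(starts[i]), int(starts[i]) + rl, "+")
        reads.append(ReadRecord(iv, sample_id, umis[i]))
    for i in dup_idx:
        reads.append(reads[int(i)])
    return reads


def simulate_rnaseq(
    genes: list[GeneModel],
    truth: GroundTruth,
    config: SynthConfig,
    genotype: str,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Negative-binomial RNA-seq counts (genes x replicates)."""
    n_rep = n_replicates or config.rnaseq_replicates
    w = np.array(
        [truth.expression[genotype][g.gene_id] * g.tx_length for g in genes]
    )
    # reference depth is anchored on wild-type abundances, so per-gene mean
    # ratios between genotypes equal the planted expression ratios exactly
    w_ref = np.array(
        [truth.expression["WT"][g.gene_id] * g.tx_length for g in genes]
    )
    mu = config.rnaseq_depth * w / w_ref.sum()
    phi = config.nb_dispersion
    cols = {}
    for rep in range(1, n_rep + 1):
        rng = rng_for(config.seed, f"{genotype}_rna_rep{rep}")
        if phi < 1e-8:
            counts = rng.poisson(mu)
        else:
            r = 1.0 / phi
            p = r / (r + mu)
            counts = rng.negative_binomial(r, p)
        cols[f"{genotype}_rna_rep{rep}"] = counts
    return pd.DataFrame(cols, index=[g.gene_id for g in genes])


# ---------------------------------------------------------------------------
# Whole experiment
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExperiment:
    config: SynthConfig
    genes: list[GeneModel]
    truth: GroundTruth
    libraries: list[SampleLibrary] = field(repr=False)
    counts: pd.DataFrame = field(repr=False)
    rna_samples: pd.DataFrame = field(repr=False)


def simulate_experiment(config: SynthConfig, n_clip_replicates: int = 2) -> SimulatedExperiment:
    """Generate the full design: 2 genotypes x IP/input x replicates, plus
    RNA-seq count matrices for both genotypes."""
    genes, truth = build_gene_set(config)
    libraries = []
    for genotype in GENOTYPES:
        for kind in ("IP", "input"):
            for rep in range(1, n_clip_replicates + 1):
                reads = simulate_clip_sample(genes, truth, config, genotype, kind, rep)
                libraries.append(
                    SampleLibrary(
                        sample_id=f"{genotype}_{kind}_rep{rep}",
                        genotype=genotype, kind=kind, replicate=rep,
                        reads=reads,
                    )
                )
    frames = [simulate_rnaseq(genes, truth, config, g) for g in GENOTYPES]
    counts = pd.concat(frames, axis=1)
    rna_samples = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "genotype": [c.split("_")[0] for c in counts.columns],
            "replicate": [int(c.rsplit("rep", 1)[1]) for c in counts.columns],
        }
    )
    return SimulatedExperiment(config, genes, truth, libraries, counts, rna_samples)
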