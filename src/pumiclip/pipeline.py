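"""End-to-end orchestration: simulate -> dedup -> call clusters ->
scan PREs -> quantify targets -> CDF statistics -> summary report.

Every stage is a pure function of its inputs plus the parameter set, so
a fixed seed and configuration reproduce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .clusters import PipelineParams, call_clusters
from .core import compute_coverage
from .expression import ExpressionMatrix, fpkm, filter_expressed, log2_fold_change, mean_by_genotype
from .motif import count_pres_near_clusters, scan_gene
from .simulate import GENOTYPES, SynthConfig, simulate_experiment
from .targets import (
    build_targets,
    cdf_compare,
    match_nontargets,
    rank_targets,
    select_occupancy_increased,
    targets_frame,
)

log = logging.getLogger("pumiclip")


@dataclass
class RunConfig:
    """Configuration of a full synthetic run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    params: PipelineParams = field(default_factory=PipelineParams)
    outdir: Path = Path("pumiclip_out")
    write_bedgraph: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            synth=SynthConfig(**d.get("synth", {})),
            params=PipelineParams(**d.get("params", {})),
            outdir=Path(d.get("outdir", "pumiclip_out")),
            write_bedgraph=bool(d.get("write_bedgraph", True)),
        )


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline on a synthetic experiment; returns the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params

    # --- stage 1: simulation ------------------------------------------------
    exp = simulate_experiment(config.synth)
    pio.write_fasta(exp.genes, out / "transcripts.fa")
    pio.write_gene_table(exp.genes, out / "genes.tsv")
    pio.write_counts(exp.counts, out / "rnaseq_counts.tsv")
    sheet = pd.DataFrame(
        [
            {"sample_id": lib.sample_id, "genotype": lib.genotype,
             "kind": lib.kind, "replicate": lib.replicate}
            for lib in exp.libraries
        ]
    )
    pio.write_sample_sheet(sheet, out / "clip_samples.tsv")
    truth = exp.truth
    pio.write_json(
        {
            "target_gene_ids": truth.target_gene_ids,
            "pre_positions": truth.pre_positions,
            "super_target_id": truth.super_target_id,
        },
        out / "ground_truth.json",
    )

    # --- stage 2: UMI dedup -------------------------------------------------
    read_counts = {}
    for lib in exp.libraries:
        n_in = len(lib.reads)
        lib.dedup()
        read_counts[lib.sample_id] = {"raw": n_in, "usable": lib.total_usable}
        log.info("dedup %s: %d -> %d reads", lib.sample_id, n_in, lib.total_usable)
        pio.write_reads_bed(lib.reads, out / f"reads_{lib.sample_id}.bed")

    if config.write_bedgraph:
        for lib in exp.libraries:
            if lib.kind != "IP":
                continue
            track = compute_coverage(lib.reads, exp.genes[0].span.chrom, "+")
            pio.write_bedgraph(track, lib.total_usable, out / f"{lib.sample_id}.bedgraph")

    # --- stage 3: cluster calling -------------------------------------------
    clusters = call_clusters(exp.libraries, params)
    log.info("called %d merged clusters", len(clusters))
    with open(out / "clusters.bed", "w") as fh:
        for c in sorted(clusters, key=lambda c: (c.interval.chrom, c.interval.start)):
            iv = c.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tcluster\t{c.max_nfc:.6g}\t{iv.strand}\n")

    # --- stage 4: PRE scan --------------------------------------------------
    sites_by_gene = {g.gene_id: scan_gene(g) for g in exp.genes}
    with open(out / "pre_sites.tsv", "w") as fh:
        fh.write("gene_id\ttx_position\tklass\n")
        for gid in sorted(sites_by_gene):
            for s in sites_by_gene[gid]:
                fh.write(f"{gid}\t{s.tx_position}\t{s.klass}\n")

    # --- stage 5: expression ------------------------------------------------
    lengths = pd.Series({g.gene_id: g.tx_length for g in exp.genes})
    matrix = filter_expressed(ExpressionMatrix(exp.counts, exp.rna_samples, lengths))
    fpkm_layer = fpkm(matrix)
    fpkm_by_genotype = {g: mean_by_genotype(fpkm_layer, matrix, g) for g in GENOTYPES}
    log2fc = log2_fold_change(matrix, "KO", "WT")

    # --- stage 6: targets ---------------------------------------------------
    gene_by_id = {g.gene_id: g for g in exp.genes}
    targets = build_targets(clusters, exp.genes, exp.libraries, fpkm_by_genotype, params)
    for t in targets:
        g = gene_by_id[t.gene_id]
        t.pre_count_near_clusters = count_pres_near_clusters(
            g, sites_by_gene[t.gene_id], t.clusters, params.pre_window
        )
    targets_frame(targets).to_csv(out / "targets.tsv", sep="\t", index=False,
                                  float_format="%.6g")

    # --- stage 7: statistics ------------------------------------------------
    report: dict = {
        "n_genes": len(exp.genes),
        "read_counts": read_counts,
        "n_clusters": len(clusters),
        "n_targets": len(targets),
        "params": asdict(params),
        "seed": config.synth.seed,
    }

    if len(targets) >= 2:
        _, rank_report = rank_targets(targets, "WT")
        report["rank"] = rank_report

    occ_wt = [t.occupancy["WT"] for t in targets if t.occupancy.get("WT") is not None]
    occ_ko = [t.occupancy["KO"] for t in targets if t.occupancy.get("KO") is not None]
    if occ_wt and occ_ko:
        occ_cmp = cdf_compare(occ_ko, occ_wt)
        ratios = [t.occupancy_ratio for t in targets if t.occupancy_ratio is not None]
        report["occupancy"] = {
            "ks_statistic": occ_cmp.ks_statistic,
            "p_value": occ_cmp.p_value,
            "n_WT": len(occ_wt),
            "n_KO": len(occ_ko),
            "median_ratio_KO_vs_WT": float(np.median(ratios)) if ratios else None,
        }
    else:
        report["occupancy"] = None

    target_ids = [t.gene_id for t in targets if t.gene_id in matrix.counts.index]
    report["derepression"] = None
    if target_ids:
        utr_lengths = pd.Series(
            {g.gene_id: len(g.utr3) for g in exp.genes}
        ).loc[matrix.counts.index]
        expr_basis = fpkm_by_genotype["WT"].clip(lower=1e-9)
        matched = match_nontargets(target_ids, expr_basis, utr_lengths,
                                   params.match_tolerance)
        if matched:
            cmp_fc = cdf_compare(log2fc.loc[target_ids], log2fc.loc[matched])
            report["derepression"] = {
                "ks_statistic": cmp_fc.ks_statistic,
                "p_value": cmp_fc.p_value,
                "n_targets": len(target_ids),
                "n_matched_nontargets": len(matched),
                "median_log2fc_targets": float(log2fc.loc[target_ids].median()),
                "median_log2fc_matched": float(log2fc.loc[matched].median()),
            }
            increased = select_occupancy_increased(targets, params.occupancy_increase_fold)
            inc_ids = [t.gene_id for t in increased if t.gene_id in log2fc.index]
            if inc_ids:
                cmp_inc = cdf_compare(log2fc.loc[inc_ids], log2fc.loc[matched])
                report["derepression_occupancy_increased"] = {
                    "ks_statistic": cmp_inc.ks_statistic,
                    "p_value": cmp_inc.p_value,
                    "n_targets": len(inc_ids),
                }

    pio.write_json(report, out / "report.json")
    return report
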