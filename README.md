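# pumiclip

Input-normalized eCLIP cluster calling and PUMILIO target-occupancy
analysis, with a fully synthetic validation harness.

## The problem

PUMILIO proteins (PUM1/PUM2) repress mRNAs by binding the 8-nt PUMILIO
response element (PRE, `UGUANAUA`) in 3'UTRs.  The abundant lncRNA
*NORAD* sequesters a large fraction of cellular PUMILIO; losing it frees
PUMILIO, increases its occupancy on target mRNAs and modestly represses
them.  Quantifying this chain of effects from CLIP-seq and RNA-seq
requires a specific stack of computations:

1. **UMI deduplication** of aligned reads; survivors are the "usable
   reads" that anchor every depth normalization.
2. **Cluster calling**: candidate bins are maximal runs of IP read
   coverage ≥ 3; for each bin the input-normalized fold-change

   `nfc = ((reads_in_bin[IP]+1)/total_usable[IP]) / ((reads_in_bin[input]+1)/total_usable[input])`

   is computed (reads count toward a bin when ≥ 50% of the read lies
   inside it); bins with `nfc ≥ 4` reproducible in both replicates of a
   genotype are clusters, and clusters overlapping ≥ 30% of the shorter
   one's length are merged.
3. **Target definition and occupancy**: genes with ≥ 1 cluster in their
   3'UTR are targets; occupancy = replicate-mean reads-per-million in
   3'UTR clusters ÷ mean FPKM (genes < 1 FPKM excluded).
4. **PRE annotation**: perfect (`UGUANAUA`) and relaxed (`UGUANAUN`,
   final base ≠ A) sites, and their proximity (≤ 100 nt) to clusters.
5. **Matched-control CDF statistics**: non-targets matched to the
   targets' mean log expression and mean 3'UTR length (± 25%), compared
   by two-sample Kolmogorov–Smirnov tests on occupancy and on
   knockout-vs-wild-type expression fold-changes.

`pumiclip` implements this pipeline as a typed, tested Python library
plus a CLI, and — because the real libraries require controlled-access
scale alignment — ships a synthetic-data generator that emulates the
study design (two genotypes × two CLIP replicates with size-matched
inputs, planted PRE sites with genotype-dependent occupancy, an optional
*Norad*-like "super-target" lncRNA carrying 11 perfect + 3 relaxed PREs,
and negative-binomial RNA-seq with ~15% target repression in the
knockout) with complete ground truth.  It is aimed at computational
biologists who want a reproducible, oracle-tested reference for this
family of CLIP analyses.

## Worked example

```bash
cat > demo.yaml <<EOF
synth:
  n_genes: 300
  reads_per_ip_sample: 6000
  reads_per_input_sample: 6000
EOF
pumiclip run-all --seed 1 --outdir demo --config demo.yaml
```

prints the per-stage log and summary:

```
INFO pumiclip: dedup WT_IP_rep1: 6000 -> 5400 reads
...
INFO pumiclip: called 90 merged clusters
90 clusters, 90 targets; report at demo/report.json
```

`demo/` then holds the transcript FASTA, gene table, per-sample BED
reads and bedGraph tracks, `clusters.bed`, `pre_sites.tsv`,
`targets.tsv` and `report.json`.  With seed 1 the report contains,
among others:

```
occupancy.median_ratio_KO_vs_WT : 1.844
derepression.ks_statistic       : 0.305
derepression.p_value            : 5.2e-04
derepression.median_log2fc_targets : -0.110
derepression.median_log2fc_matched :  0.113
```

Reading: the 90 planted targets (of 300 genes) were all recovered as
CLIP targets; their knockout/wild-type occupancy ratio centers near the
planted 2× multiplier (compressed slightly by depth normalization, see
`docs/methods.md`); and their expression fold-change CDF is left-shifted
relative to 81 expression- and UTR-matched non-targets (KS p ≈ 5×10⁻⁴),
the synthetic analog of PUMILIO-target derepression.

The same stages are available piecemeal (`pumiclip simulate`, `dedup`,
`call-clusters`, `scan-pre`) and as library functions
(`pumiclip.call_clusters`, `scan_pre`, `build_targets`,
`match_nontargets`, `cdf_compare`, ...).

## Layout

```
src/pumiclip/
  core.py        intervals, reads, gene models, coverage
  io.py          BED6 / bedGraph / FASTA / TSV readers and writers
  preprocess.py  UMI deduplication, usable-read accounting
  clusters.py    the cluster caller and its thresholds
  motif.py       PRE scanning and PRE-cluster proximity
  expression.py  CPM/FPKM, expressed-gene filter, fold-changes
  targets.py     targets, occupancy, matched controls, KS statistics
  simulate.py    synthetic experiment generator with ground truth
  pipeline.py    run-all orchestration and report
  cli.py         command-line interface
docs/methods.md  models, parameter rationale, limitations
tests/           unit, property and end-to-end suites with
                 independent brute-force oracles (tests/_reference.py)
```
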