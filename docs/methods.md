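# Methods

This note documents the models, parameters and numerical choices behind
`pumiclip`: an input-normalized CLIP-seq cluster caller with downstream
PUMILIO-target statistics, and the synthetic-data generator used to
validate every stage against planted ground truth.

## The cluster caller

The caller reproduces a classical input-normalized eCLIP analysis with
four thresholds, all exposed in `PipelineParams`:

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 3 | per-base IP coverage floor defining candidate bins |
| `read_bin_overlap_frac` | 0.5 | fraction of a read's length that must fall inside a bin for the read to count |
| `min_fold_change` | 4 | input-normalized fold-change cutoff |
| `merge_frac` | 0.3 | reciprocal-overlap fraction (of the shorter cluster) for merging |

Candidate bins are maximal runs of consecutive positions whose IP read
coverage is at least `min_coverage`; no sliding windows are used.
Coverage and all counting are strand-specific.  For each bin the
normalized fold-change is

```
nfc = ((reads_in_bin[IP] + 1) / total_usable[IP])
    / ((reads_in_bin[input] + 1) / total_usable[input])
```

where `total_usable` is the library size after UMI deduplication.  Bins
with `nfc >= 4` are per-replicate clusters.  A cluster is kept when it
overlaps (>= 1 bp) a cluster from the other biological replicate of the
same genotype; clusters reproducible in both genotypes are annotated
`both`.  Finally, clusters overlapping by at least 30% of the shorter
cluster's length are merged to a fixed point.  Because pairwise merging
is not intrinsically order-independent, the implementation always merges
the leftmost qualifying pair in coordinate-sorted order and re-scans;
this makes the fixed point deterministic, and the test suite checks it
against an independent all-pairs brute-force reference.  Per-replicate
read counts and fold-changes of merged intervals are recomputed from the
libraries over the union interval with the same 50% rule.

UMI deduplication keys reads on `(chrom, start, strand, UMI)`.  The read
end is deliberately excluded — adapter trimming can shorten otherwise
identical molecules — and ties are broken deterministically (shortest
read, then input order), so pipelines are byte-reproducible.

Degenerate inputs: an empty usable-read library is an error (the
normalization is undefined); an IP/input pair with mismatched genotype
or replicate is a pairing error; fewer than two replicates in every
genotype makes the reproducibility filter impossible and raises.

## Target statistics

A gene is a target when at least one merged cluster overlaps its 3'UTR
(>= 1 bp, same strand); a cluster overlapping two genes' UTRs counts for
both.  Per-gene CLIP signal is the depth-weighted sum of cluster reads:
reads in each 3'UTR cluster (50% rule) scaled to reads-per-million of
that replicate's usable reads, summed over clusters and replicates.
Occupancy divides the replicate-mean of this signal by the gene's mean
FPKM in the same genotype and is undefined (the gene is excluded, not an
error) below `min_fpkm = 1`.

Matched non-targets are selected with one global window around the
target set's means: non-targets whose log10 expression lies within 25%
(fractionally) of the targets' mean log10 expression and whose 3'UTR
length lies within 25% of the targets' mean UTR length, boundaries
inclusive.  When the mean log expression is exactly 0 the fractional
window is empty and the function raises with guidance to rescale, rather
than guessing a semantics.  Distribution shifts (occupancy between
genotypes; fold-changes of targets vs matched non-targets) are scored
with the two-sample two-sided Kolmogorov–Smirnov test
(`scipy.stats.ks_2samp`, exact p-values for small samples, asymptotic
otherwise); the D statistic is verified against a brute-force empirical
CDF gap enumeration in the tests.

Per-gene expression fold-changes are `log2((mean CPM + 1)/(mean CPM + 1))`
between genotypes.  A generalized-linear differential-expression model
is deliberately not used: the downstream analyses are distribution-level
CDF comparisons that need only a per-gene point estimate, and the
pseudocounted CPM ratio is transparent and dependency-free.  The
pseudocount shrinks fold-changes of very low-expression genes toward 0;
matched non-targets occupy the same expression window as targets, so the
comparison is unbiased even though individual low-expression genes are
attenuated.

PRE annotation: the perfect PUMILIO response element is the octamer
UGUANAUA; the relaxed consensus UGUANAUN allows any final base, and a
site is classified `relaxed` only when the final base is not A, so the
classes are disjoint.  Overlapping occurrences each count once.  T is
mapped to U before matching.  The PRE–cluster proximity filter counts
sites whose octamer lies within 100 nt (edge-to-edge gap, boundary
inclusive) of any 3'UTR cluster of the gene.

## The synthetic-data generator

The generator (`simulate` module) emulates the structure of a
two-genotype brain eCLIP study — wild-type (`WT`) and lncRNA-knockout
(`KO`), two CLIP replicates per genotype, each IP paired with a
size-matched input, plus RNA-seq count matrices — with every planted
feature recorded in a `GroundTruth` object.

Genome and genes: single-exon genes on the plus strand of one synthetic
chromosome, non-overlapping, 6 kb transcripts with 1 kb 3'UTRs (long
transcripts typical of neural tissue).  Background sequence is drawn
uniformly and rejection-sampled so that no UGUANAU heptamer exists
outside planted octamers; redrawing never touches planted bases, so
planted site counts are exact.  30% of genes are targets carrying two
perfect PREs 40 nt apart at a random position in the 3'UTR.  Expression
is log-uniform over [1, 1000] FPKM-equivalents.

Reads: input reads fall uniformly within transcripts, genes weighted by
expression × length.  IP reads add a site component: each target gene
receives site weight

```
(ip_site_enrichment - 1) × site_reference_expression × tx_length
```

shared equally among its planted sites and multiplied by
`ko_occupancy_multiplier` in the knockout, so `ip_site_enrichment = 1`
reduces exactly to the input distribution (the null).  A site read is
placed so the octamer is uniformly positioned within the read,
approximating a crosslink pileup spanning the motif.  Site strength is
independent of host-gene abundance — modelling high-affinity sites that
saturate the immunoprecipitation — which keeps planted sites detectable
across the whole expression range and makes the super-target's rank
ratio meaningful.  Each library emits a fixed number of reads
(default 2,000 per sample for the 100-gene gene set; analyses with more
genes scale reads proportionally, ~20 IP reads per gene), of which a
configurable fraction (default 10%) are exact PCR duplicates (same
position and UMI, 10-nt UMIs).

Defaults were chosen by analyzing the generative model once, before the
validation suite was frozen: site pileups (~15–30 reads per site) must
clear the coverage floor of 3 while background coverage stays below it
even for the most abundant genes (35-nt reads on 6-kb transcripts give
peak background coverage ≈ 1–2), and the planted-site share of the IP
library (~25%) must remain a minority so that depth normalization does
not erase the knockout occupancy shift.  `site_reference_expression = 30`
expresses site strength in transcript-abundance-equivalents per
enrichment fold.

Super-target: with `super_target=True` one extra noncoding gene
(`synNorad`, 5.2 kb, whole transcript treated as its 3'UTR) is added
with 11 perfect and 3 relaxed-only planted PREs and a site weight of
`super_target_fold` (default 2000) × the median mRNA-target site weight,
identical in both genotypes.  The flag is off by default: a gene
absorbing ~95% of the IP library starves every mRNA-level analysis at
desk-scale depth, so it is enabled only for the ranking analysis and the
demo configuration.

RNA-seq: negative-binomial counts with variance `mu + phi mu^2`
(default dispersion `phi = 0.1`, the standard bulk RNA-seq noise
family), three replicates per genotype, default depth 5 × 10^6.  Target
means in the knockout are scaled by `1 - repression_fraction`
(default 0.15, a modest repression).  Both genotypes are normalized
against the wild-type abundance sum, so planted per-gene mean ratios are
exact and knockout column totals fall slightly below the nominal depth,
as they would when sequencing equal amounts of material.

Reproducibility: one global seed; each sample's RNG is derived from the
seed plus a CRC32 hash of its label, so any single sample can be
regenerated independently of generation order, and a fixed seed plus
configuration reproduces byte-identical pipeline outputs.

### What the generator does and does not emulate

It reproduces the statistical skeleton the analysis relies on: paired
IP/input libraries with planted, strand-specific, motif-centred
enrichment; genotype-dependent occupancy; a dominant noncoding binder;
NB expression noise with modest target repression.  It does not model
spliced transcripts (transcript and genomic coordinates are related by a
fixed offset), sequencing errors or quality scores, crosslink-site
truncation biases, non-uniform fragmentation, UMI sequencing errors
(no edit-distance collapsing is performed), mappability, or binding
outside 3'UTRs.  Passing tests therefore demonstrate correctness of the
computational pipeline under its stated assumptions, not performance on
real libraries, where bin boundaries and input structure are messier.

## Validation experiment sizes

The validation suite runs desk-scale experiment sizes chosen to give
each statistical claim adequate power: planted-site recovery and null
calibration use 10 experiments of 100 genes (2,000 reads per library);
the occupancy-shift analysis uses ten 1,000-gene experiments for the
median-ratio estimate and one 4,000-gene experiment (~1,200 targets) for
the KS comparison — with ~3 decades of occupancy spread, a 2× shift
(D ≈ 0.1) needs on the order of a thousand targets per group to clear
p < 0.01 in a single experiment; the derepression analysis uses
1,500-gene experiments (450 targets, ~270 matched non-targets).  The
KO/WT occupancy ratio expected under the defaults is ≈ 1.7–1.9 rather
than exactly 2: depth normalization against a library whose site
component doubled compresses the ratio, and the knockout's repressed
target expression (smaller FPKM denominator) partially restores it.

## Known limitations

- The 25% matching window is applied to the target set's mean (one
  global window), not per-target 1:1 matching; with heterogeneous
  targets the control set matches the mean, not the shape, of the
  expression distribution.
- Merged clusters spanning replicate-specific bins recompute counts on
  the union interval; a replicate with sub-threshold signal still
  contributes its (small) counts there.
- The caller assigns no statistical significance to individual clusters
  (no Poisson/binomial peak p-values); only distribution-level KS tests
  are reported downstream.
- For multi-exon genes the PRE–cluster distance would be ambiguous
  (genomic vs spliced); the synthetic genome is single-exon, and real
  data would need caller-supplied genomic PRE coordinates.
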