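"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately naive — per-base scans, per-read loops,
all-pairs comparisons — and shares no code with the package paths it
checks (only the frozen data types are reused).
"""

from __future__ import annotations

from pumiclip.core import GenomicInterval


def coverage_brute(reads, chrom, strand, span):
    """Per-base coverage by explicit position membership tests."""
    lo, hi = span
    values = []
    for pos in range(lo, hi):
        n = 0
        for r in reads:
            iv = r.interval
            if iv.chrom == chrom and iv.strand == strand and iv.start <= pos < iv.end:
                n += 1
        values.append(n)
    return values


def bins_brute(values, span_start, chrom, strand, min_coverage):
    """Maximal runs >= min_coverage by linear scan."""
    bins = []
    start = None
    for i, v in enumerate(values):
        if v >= min_coverage and start is None:
            start = i
        elif v < min_coverage and start is not None:
            bins.append(GenomicInterval(chrom, span_start + start, span_start + i, strand))
            start = None
    if start is not None:
        bins.append(GenomicInterval(chrom, span_start + start, span_start + len(values), strand))
    return bins


def count_reads_brute(reads, region, frac):
    n = 0
    for r in reads:
        iv = r.interval
        if iv.chrom != region.chrom or iv.strand != region.strand:
            continue
        ov = min(iv.end, region.end) - max(iv.start, region.start)
        if ov >= frac * (iv.end - iv.start):
            n += 1
    return n


def nfc_brute(ip_n, input_n, ip_total, input_total):
    return ((ip_n + 1) / ip_total) / ((input_n + 1) / input_total)


def per_replicate_bins_brute(ip, inp, params):
    """Retained bins of one IP/input pair, fully per-base / per-read."""
    keys = sorted({(r.interval.chrom, r.interval.strand) for r in ip.reads})
    out = []
    for chrom, strand in keys:
        sel = [r for r in ip.reads
               if r.interval.chrom == chrom and r.interval.strand == strand]
        lo = min(r.interval.start for r in sel)
        hi = max(r.interval.end for r in sel)
        values = coverage_brute(sel, chrom, strand, (lo, hi))
        for b in bins_brute(values, lo, chrom, strand, params.min_coverage):
            ip_n = count_reads_brute(ip.reads, b, params.read_bin_overlap_frac)
            in_n = count_reads_brute(inp.reads, b, params.read_bin_overlap_frac)
            nfc = nfc_brute(ip_n, in_n, ip.total_usable, inp.total_usable)
            if nfc >= params.min_fold_change:
                out.append((b, ip_n, in_n, nfc))
    return out


def _overlap(a, b):
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reproducible_brute(per_rep, params):
    """All-pairs reproducibility check; returns [(genotype, rep, bin)]."""
    genotypes = sorted({g for g, _ in per_rep})
    kept = []
    for g in genotypes:
        reps = sorted(r for gg, r in per_rep if gg == g)
        if len(reps) < 2:
            continue
        for r in reps:
            partner_bins = [b for r2 in reps if r2 != r for b in per_rep[(g, r2)]]
            for b in per_rep[(g, r)]:
                if any(_overlap(b[0], o[0]) >= 1 for o in partner_bins):
                    kept.append((g, r, b))
    return kept


def merge_brute(intervals, merge_frac, recount_counts):
    """Leftmost-first fixed-point merging on plain intervals.

    ``recount_counts(interval)`` -> per-replicate maps, used only so the
    caller can compare counts afterwards; merging decisions use interval
    geometry alone.
    """
    work = sorted(intervals, key=lambda iv: (iv.chrom, iv.strand, iv.start, iv.end))
    while True:
        merged_one = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                a, b = work[i], work[j]
                ov = _overlap(a, b)
                if ov >= merge_frac * min(a.end - a.start, b.end - b.start):
                    union = GenomicInterval(a.chrom, min(a.start, b.start),
                                            max(a.end, b.end), a.strand)
                    work = [iv for k, iv in enumerate(work) if k not in (i, j)]
                    work.append(union)
                    work.sort(key=lambda iv: (iv.chrom, iv.strand, iv.start, iv.end))
                    merged_one = True
                    break
            if merged_one:
                break
        if not merged_one:
            return [(iv, recount_counts(iv)) for iv in work]


def ks_statistic_brute(a, b):
    """Sup gap of the two empirical CDFs, evaluated at every data point."""
    a = sorted(a)
    b = sorted(b)
    points = sorted(set(a) | set(b))
    d = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def scan_pre_brute(seq):
    """Character-by-character PRE scan; returns [(pos, klass)]."""
    s = seq.upper().replace("T", "U")
    hits = []
    for i in range(len(s) - 7):
        w = s[i : i + 8]
        if (w[0:4] == "UGUA" and w[4] in "ACGU" and w[5:7] == "AU"
                and w[7] in "ACGU"):
            hits.append((i, "perfect" if w[7] == "A" else "relaxed"))
    return hits
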