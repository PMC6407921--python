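import numpy as np
import pytest

from pumiclip.clusters import (
    CandidateBin,
    ClipCluster,
    PipelineParams,
    call_candidate_bins,
    call_clusters,
    call_clusters_per_replicate,
    count_reads_in_region,
    filter_reproducible,
    merge_clusters,
    normalized_fold_change,
)
from pumiclip.core import CoverageTrack, GenomicInterval
from pumiclip.preprocess import SampleLibrary

from . import _reference as ref
from .conftest import make_read


def track(values, start=0, chrom="c", strand="+"):
    return CoverageTrack(chrom, strand, start, np.asarray(values, dtype=np.int64))


class TestCandidateBins:
    def test_runs_at_or_above_floor(self):
        bins = call_candidate_bins(track([1, 3, 4, 3, 0, 5, 2]), min_coverage=3)
        assert [(b.start, b.end) for b in bins] == [(1, 4), (5, 6)]

    def test_all_zero_and_all_high(self):
        assert call_candidate_bins(track([0, 0, 0]), 3) == []
        bins = call_candidate_bins(track([7, 7, 7], start=50), 3)
        assert [(b.start, b.end) for b in bins] == [(50, 53)]

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            values = rng.poisson(2.0, size=int(rng.integers(1, 300)))
            got = call_candidate_bins(track(values, start=17), 3)
            exp = ref.bins_brute(values.tolist(), 17, "c", "+", 3)
            assert [(b.start, b.end) for b in got] == [(b.start, b.end) for b in exp]


class TestReadCounting:
    def test_half_overlap_boundary(self):
        region = GenomicInterval("c", 15, 40)
        inside = [make_read("c", 10, 20)]   # overlap 5 of 10 -> counted
        assert count_reads_in_region(inside, region, 0.5) == 1
        region2 = GenomicInterval("c", 16, 40)  # overlap 4 of 10 -> dropped
        assert count_reads_in_region(inside, region2, 0.5) == 0

    def test_fully_contained_read(self):
        region = GenomicInterval("c", 0, 100)
        assert count_reads_in_region([make_read("c", 40, 60)], region, 0.5) == 1

    def test_strand_specific(self):
        region = GenomicInterval("c", 0, 100)
        assert count_reads_in_region([make_read("c", 40, 60, "-")], region, 0.5) == 0


class TestNormalizedFoldChange:
    @pytest.mark.parametrize(
        "ip, inp, ip_total, input_total, expected",
        [
            (7, 1, 10**6, 10**6, 4.0),
            (0, 0, 123, 123, 1.0),
            (0, 0, 10**7, 10**7, 1.0),
            (19, 4, 2 * 10**6, 10**6, 2.0),
        ],
    )
    def test_printed_formula(self, ip, inp, ip_total, input_total, expected):
        assert normalized_fold_change(ip, inp, ip_total, input_total) == pytest.approx(
            expected, abs=1e-12
        )

    def test_empty_library_is_an_error(self):
        with pytest.raises(ValueError, match="empty usable-read library"):
            normalized_fold_change(1, 1, 0, 10)


def _libraries_from_reads(reads_by_sample):
    libs = []
    for (genotype, kind, rep), reads in reads_by_sample.items():
        lib = SampleLibrary(f"{genotype}_{kind}_rep{rep}", genotype, kind, rep, reads)
        lib.dedup()
        libs.append(lib)
    return libs


class TestReproducibility:
    def _bin(self, start, end, nfc=5.0):
        return CandidateBin(GenomicInterval("c", start, end), 5, 0, 100, 100, nfc)

    def test_kept_when_both_replicates_of_one_genotype_overlap(self):
        per_rep = {
            ("WT", 1): [self._bin(0, 50)],
            ("WT", 2): [self._bin(40, 90)],
            ("KO", 1): [],
            ("KO", 2): [],
        }
        kept = filter_reproducible(per_rep)
        assert {(c.interval.start, c.interval.end) for c in kept} == {(0, 50), (40, 90)}
        assert all(c.supporting_genotype == "WT" for c in kept)

    def test_dropped_when_only_across_genotypes(self):
        per_rep = {
            ("WT", 1): [self._bin(0, 50)],
            ("WT", 2): [],
            ("KO", 1): [self._bin(10, 60)],
            ("KO", 2): [],
        }
        assert filter_reproducible(per_rep) == []

    def test_both_genotype_annotation(self):
        per_rep = {
            ("WT", 1): [self._bin(0, 50)],
            ("WT", 2): [self._bin(0, 50)],
            ("KO", 1): [self._bin(10, 60)],
            ("KO", 2): [self._bin(10, 60)],
        }
        kept = filter_reproducible(per_rep)
        assert kept and all(c.supporting_genotype == "both" for c in kept)

    def test_requires_two_replicates_somewhere(self):
        with pytest.raises(ValueError, match="replicates"):
            filter_reproducible({("WT", 1): [], ("KO", 1): []})

    def test_empty_input_empty_output(self):
        assert filter_reproducible({("WT", 1): [], ("WT", 2): []}) == []


class TestMerging:
    def _cluster(self, start, end):
        return ClipCluster(GenomicInterval("c", start, end),
                           {("WT", 1): 5.0}, {("WT", 1): 5}, {("WT", 1): 0}, "WT")

    def test_thirty_percent_boundary_merges(self):
        merged = merge_clusters([self._cluster(0, 100), self._cluster(70, 170)], 0.3)
        assert [(c.interval.start, c.interval.end) for c in merged] == [(0, 170)]

    def test_below_boundary_does_not_merge(self):
        merged = merge_clusters([self._cluster(0, 100), self._cluster(71, 171)], 0.3)
        assert len(merged) == 2

    def test_disjoint_unchanged(self):
        merged = merge_clusters([self._cluster(0, 50), self._cluster(200, 260)], 0.3)
        assert len(merged) == 2

    def test_chain_merges_to_fixed_point(self):
        chain = [self._cluster(0, 100), self._cluster(70, 170), self._cluster(140, 240)]
        merged = merge_clusters(chain, 0.3)
        assert [(c.interval.start, c.interval.end) for c in merged] == [(0, 240)]

    def test_fraction_relative_to_shorter(self):
        # 20 bp overlap: 10% of the 200-long, but 40% of the 50-long cluster
        merged = merge_clusters([self._cluster(0, 200), self._cluster(180, 230)], 0.3)
        assert len(merged) == 1

    def test_result_satisfies_non_overlap_invariant(self):
        rng = np.random.default_rng(5)
        clusters = [self._cluster(int(s), int(s) + int(l))
                    for s, l in zip(rng.integers(0, 500, 40), rng.integers(10, 120, 40))]
        merged = merge_clusters(clusters, 0.3)
        for i, a in enumerate(merged):
            for b in merged[i + 1:]:
                ov = max(0, min(a.interval.end, b.interval.end)
                         - max(a.interval.start, b.interval.start))
                assert ov < 0.3 * min(len(a.interval), len(b.interval))


def _random_instance(seed):
    """Small random 2-genotype x 2-replicate experiment, arbitrary reads."""
    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(1, 6))
    span = n_genes * 400
    libs = {}
    for genotype in ("WT", "KO"):
        for rep in (1, 2):
            for kind in ("IP", "input"):
                n = int(rng.integers(20, 500))
                reads = []
                for _ in range(n):
                    start = int(rng.integers(0, span - 20))
                    length = int(rng.integers(20, 80))
                    strand = "+" if rng.random() < 0.8 else "-"
                    umi = "".join(rng.choice(list("ACGT"), 6))
                    reads.append(make_read("c", start, start + length, strand, umi,
                                           f"{genotype}_{kind}_rep{rep}"))
                libs[(genotype, kind, rep)] = reads
    return _libraries_from_reads(libs)


class TestCallerAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(20))
    def test_full_caller_matches_naive_reference(self, seed):
        """Bins, retained clusters and merged clusters agree exactly with a
        per-base / per-read / all-pairs reference on random instances."""
        params = PipelineParams()
        libs = _random_instance(seed)
        by_key = {(l.genotype, l.kind, l.replicate): l for l in libs}

        per_rep_got = {}
        per_rep_exp = {}
        for genotype in ("WT", "KO"):
            for rep in (1, 2):
                ip = by_key[(genotype, "IP", rep)]
                inp = by_key[(genotype, "input", rep)]
                got = call_clusters_per_replicate(ip, inp, params)
                exp = ref.per_replicate_bins_brute(ip, inp, params)
                assert [
                    ((b.interval.chrom, b.interval.strand, b.interval.start,
                      b.interval.end), b.ip_reads, b.input_reads, b.nfc)
                    for b in got
                ] == [
                    ((b.chrom, b.strand, b.start, b.end), ipn, inn, nfc)
                    for b, ipn, inn, nfc in exp
                ]
                per_rep_got[(genotype, rep)] = got
                per_rep_exp[(genotype, rep)] = [
                    CandidateBin(b, ipn, inn, ip.total_usable, inp.total_usable, nfc)
                    for b, ipn, inn, nfc in exp
                ]

        kept_got = filter_reproducible(per_rep_got, params)
        kept_exp = ref.reproducible_brute(
            {k: [(b.interval, b.ip_reads, b.input_reads, b.nfc) for b in v]
             for k, v in per_rep_exp.items()},
            params,
        )
        got_set = sorted(
            ((c.interval.chrom, c.interval.strand, c.interval.start, c.interval.end),
             next(iter(c.nfc.items())))
            for c in kept_got
        )
        exp_set = sorted(
            (((b[0].chrom, b[0].strand, b[0].start, b[0].end)), ((g, r), b[3]))
            for g, r, b in kept_exp
        )
        assert got_set == exp_set

        merged_got = call_clusters(libs, params)
        merged_exp = ref.merge_brute(
            [b[0] for _, _, b in kept_exp], params.merge_frac,
            lambda iv: None,
        )
        assert sorted(
            (c.interval.chrom, c.interval.strand, c.interval.start, c.interval.end)
            for c in merged_got
        ) == sorted((iv.chrom, iv.strand, iv.start, iv.end) for iv, _ in merged_exp)

        # recomputed per-replicate counts on merged intervals match per-read loops
        for c in merged_got:
            for (genotype, rep), n in c.ip_reads.items():
                lib = by_key[(genotype, "IP", rep)]
                assert n == ref.count_reads_brute(
                    lib.reads, c.interval, params.read_bin_overlap_frac
                )


class TestMonotonicity:
    def test_raising_fold_change_keeps_a_subset(self):
        libs = _random_instance(99)
        by_key = {(l.genotype, l.kind, l.replicate): l for l in libs}
        ip, inp = by_key[("WT", "IP", 1)], by_key[("WT", "input", 1)]
        loose = {(b.interval.start, b.interval.end)
                 for b in call_clusters_per_replicate(ip, inp, PipelineParams())}
        tight = {(b.interval.start, b.interval.end)
                 for b in call_clusters_per_replicate(
                     ip, inp, PipelineParams(min_fold_change=8))}
        assert tight <= loose

    def test_raising_coverage_floor_shrinks_candidate_bins(self):
        from pumiclip.core import compute_coverage

        libs = _random_instance(99)
        ip = next(l for l in libs if (l.genotype, l.kind, l.replicate) == ("WT", "IP", 1))
        trk = compute_coverage(ip.reads, "c", "+")
        loose = call_candidate_bins(trk, 3)
        tight = call_candidate_bins(trk, 5)
        for b in tight:
            assert any(b.start >= a.start and b.end <= a.end for a in loose)

    def test_pairing_mismatch_is_an_error(self):
        libs = _random_instance(1)
        by_key = {(l.genotype, l.kind, l.replicate): l for l in libs}
        with pytest.raises(ValueError, match="pairing mismatch"):
            call_clusters_per_replicate(by_key[("WT", "IP", 1)],
                                        by_key[("KO", "input", 1)])
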