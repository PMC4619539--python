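import numpy as np
import pytest

from _oracles import brute_force_hotspots, per_base_depth
from conftest import random_amplicon_map
from mcrkit.copy_calling import CopyState
from mcrkit.hotspots import (
    amplified_intervals,
    annotate_genes,
    associate_with_covariate,
    build_support_profile,
    find_hotspots,
    find_hotspots_multi,
)
from mcrkit.io import GeneRecord, GenomicInterval, SegmentRecord


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestAmplifiedIntervals:
    def test_only_amplified_segments_kept(self):
        segs = [
            SegmentRecord("S1", "chr1", 100, 1000, 1.0),   # ratio 2.0 -> AMP
            SegmentRecord("S1", "chr1", 1001, 2000, 0.0),  # diploid
        ]
        result = amplified_intervals(segs)
        assert result == {"S1": [iv(100, 1000)]}

    def test_abutting_amplified_segments_merged(self):
        segs = [
            SegmentRecord("S1", "chr1", 100, 1000, 1.0),
            SegmentRecord("S1", "chr1", 1001, 2000, 1.2),
        ]
        assert amplified_intervals(segs) == {"S1": [iv(100, 2000)]}

    def test_gap_larger_than_merge_gap_not_merged(self):
        segs = [
            SegmentRecord("S1", "chr1", 100, 1000, 1.0),
            SegmentRecord("S1", "chr1", 1500, 2000, 1.0),
        ]
        assert amplified_intervals(segs) == {"S1": [iv(100, 1000), iv(1500, 2000)]}
        assert amplified_intervals(segs, merge_gap=499) == {"S1": [iv(100, 2000)]}

    def test_empty_input(self):
        assert amplified_intervals([]) == {}

    def test_gain_included_on_request(self):
        segs = [SegmentRecord("S1", "chr1", 100, 1000, 0.58)]  # ratio ~1.49 GAIN
        assert amplified_intervals(segs) == {}
        assert amplified_intervals(segs, include_gain=True) == {"S1": [iv(100, 1000)]}


class TestSupportProfile:
    def test_two_interval_sweep(self):
        profile = build_support_profile(
            {"A": [iv(100, 1000)], "B": [iv(500, 1500)]}, "chr1"
        )
        spans = list(zip(profile.starts, profile.ends, profile.depth))
        assert spans == [(100, 499, 1), (500, 1000, 2), (1001, 1500, 1)]

    def test_distinct_sample_counting(self):
        profile = build_support_profile(
            {"A": [iv(100, 1000), iv(500, 1500)]}, "chr1"
        )
        assert set(profile.depth) == {1}
        assert profile.depth_at(700) == 1

    def test_wrong_chromosome_rejected(self):
        with pytest.raises(ValueError):
            build_support_profile({"A": [iv(1, 10, chrom="chr2")]}, "chr1")

    def test_matches_per_base_oracle_on_random_input(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            amplicons = random_amplicon_map(rng, n_samples=10, chrom_length=10_000)
            profile = build_support_profile(amplicons, "chr1")
            depth = per_base_depth(amplicons, 10_000)
            for s, e, d in zip(profile.starts, profile.ends, profile.depth):
                assert depth[s] == d and depth[e] == d
                mid = (s + e) // 2
                assert depth[mid] == d
            covered = np.zeros(10_002, dtype=bool)
            for s, e in zip(profile.starts, profile.ends):
                covered[s : e + 1] = True
            assert np.array_equal(covered[1:10_001], depth[1:10_001] > 0)


class TestFindHotspots:
    def test_three_way_intersection(self):
        profile = build_support_profile(
            {"A": [iv(100, 1000)], "B": [iv(500, 1500)], "C": [iv(800, 1200)]},
            "chr1",
        )
        (h,) = find_hotspots(profile, min_support=3)
        assert (h.interval.start, h.interval.end) == (800, 1000)
        assert h.support == 3
        assert h.supporting_samples == frozenset({"A", "B", "C"})

    def test_two_samples_insufficient(self):
        profile = build_support_profile(
            {"A": [iv(100, 1000)], "B": [iv(500, 1500)]}, "chr1"
        )
        assert find_hotspots(profile, min_support=3) == []

    def test_long_plateau_discarded(self):
        amplicons = {s: [iv(1_000_000, 4_000_000)] for s in "ABC"}
        profile = build_support_profile(amplicons, "chr1")
        assert find_hotspots(profile, min_support=3, max_length=2_500_000) == []
        kept = find_hotspots(profile, min_support=3, max_length=3_000_001)
        assert len(kept) == 1

    def test_min_support_below_one_rejected(self):
        profile = build_support_profile({"A": [iv(1, 10)]}, "chr1")
        with pytest.raises(ValueError):
            find_hotspots(profile, min_support=0)

    def test_hotspot_subset_of_supporting_amplicons(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            amplicons = random_amplicon_map(rng, n_samples=8, chrom_length=50_000)
            profile = build_support_profile(amplicons, "chr1")
            for h in find_hotspots(profile, min_support=3, max_length=50_000):
                for sample in h.supporting_samples:
                    covered = np.zeros(50_002, dtype=bool)
                    for a in amplicons[sample]:
                        covered[a.start : a.end + 1] = True
                    assert covered[h.interval.start : h.interval.end + 1].all()

    def test_raising_min_support_never_enlarges(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            amplicons = random_amplicon_map(rng, n_samples=10, chrom_length=50_000)
            profile = build_support_profile(amplicons, "chr1")
            lower = find_hotspots(profile, min_support=3, max_length=50_000)
            higher = find_hotspots(profile, min_support=4, max_length=50_000)
            assert len(higher) <= len(lower)
            lower_set = {(h.interval, h.support) for h in lower}
            for h in higher:
                assert (h.interval, h.support) in lower_set

    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            amplicons = random_amplicon_map(rng, n_samples=10, chrom_length=20_000)
            profile = build_support_profile(amplicons, "chr1")
            got = [
                (h.interval.start, h.interval.end, h.support)
                for h in find_hotspots(profile, min_support=3, max_length=20_000)
            ]
            expected = brute_force_hotspots(amplicons, 20_000, 3, 20_000)
            assert got == expected


class TestAnnotateGenes:
    GENES = [
        GeneRecord("gA", "chr1", 150, 250),
        GeneRecord("gB", "chr1", 301, 400),
        GeneRecord("gC", "chr1", 280, 320),
    ]

    def hotspot(self, start, end):
        return find_hotspots(
            build_support_profile({s: [iv(start, end)] for s in "ABC"}, "chr1"),
            min_support=3,
        )[0]

    def test_one_bp_overlap_assigned(self):
        annotated, _ = annotate_genes([self.hotspot(200, 300)], self.GENES)
        assert annotated[0].genes == ("gA", "gC")

    def test_abutting_gene_not_assigned(self):
        annotated, _ = annotate_genes([self.hotspot(200, 300)], [self.GENES[1]])
        assert annotated[0].genes == ()

    def test_unique_count_deduplicates(self):
        genes = [
            GeneRecord("g1", "chr1", 100, 200),
            GeneRecord("g2", "chr1", 150, 450),  # overlaps both hotspots
            GeneRecord("g3", "chr1", 400, 500),
            GeneRecord("g4", "chr1", 460, 520),
            GeneRecord("g5", "chr2", 100, 200),
        ]
        hs = [self.hotspot(100, 250), self.hotspot(420, 470)]
        annotated, unique = annotate_genes(hs, genes)
        n_assignments = sum(len(h.genes) for h in annotated)
        assert n_assignments == 5
        assert unique == 4


class TestCovariateAssociation:
    def test_exact_u_and_p_for_separated_groups(self):
        """amplified {4,5,6} vs diploid {1,2,3}: U = 9 (maximal),
        one-sided exact p = 1/C(6,3) = 0.05."""
        states = {f"A{i}": CopyState.AMPLIFICATION for i in range(3)}
        states.update({f"D{i}": CopyState.DIPLOID for i in range(3)})
        cov = {"A0": 4, "A1": 5, "A2": 6, "D0": 1, "D1": 2, "D2": 3}
        (res,) = associate_with_covariate(
            states, cov,
            contrasts=[(CopyState.AMPLIFICATION, CopyState.DIPLOID)],
            alternative="greater",
        )
        assert res.u_statistic == 9
        assert res.p_value == pytest.approx(0.05)
        assert res.method == "exact"

    def test_identical_groups_p_one(self):
        states = {"A": CopyState.GAIN, "B": CopyState.GAIN,
                  "C": CopyState.DIPLOID, "D": CopyState.DIPLOID}
        cov = {"A": 2.0, "B": 3.0, "C": 2.0, "D": 3.0}
        (res,) = associate_with_covariate(
            states, cov, contrasts=[(CopyState.GAIN, CopyState.DIPLOID)]
        )
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_flagged_not_raised(self):
        states = {"A": CopyState.AMPLIFICATION, "B": CopyState.AMPLIFICATION}
        cov = {"A": 4.0, "B": 5.0}
        res = associate_with_covariate(states, cov)
        assert all(not r.computable for r in res)

    def test_medians_and_default_contrasts(self):
        states = {
            "A1": CopyState.AMPLIFICATION, "A2": CopyState.AMPLIFICATION,
            "A3": CopyState.AMPLIFICATION,
            "G1": CopyState.GAIN, "G2": CopyState.GAIN,
            "D1": CopyState.DIPLOID, "D2": CopyState.DIPLOID, "D3": CopyState.DIPLOID,
        }
        cov = {"A1": 4.7, "A2": 5.1, "A3": 1.6, "G1": 3.0, "G2": 2.5,
               "D1": 2.3, "D2": 1.5, "D3": 3.0}
        gain_res, amp_res = associate_with_covariate(states, cov)
        assert (gain_res.group1, gain_res.group2) == (CopyState.GAIN, CopyState.DIPLOID)
        assert gain_res.median1 == pytest.approx(np.median([3.0, 2.5]))
        assert amp_res.median1 == pytest.approx(np.median([4.7, 5.1, 1.6]))
        assert amp_res.median2 == pytest.approx(np.median([2.3, 1.5, 3.0]))
        assert amp_res.range1 == (1.6, 5.1)


class TestMultiChromosome:
    def test_hotspots_found_per_chromosome(self):
        amplicons = {
            "A": [iv(100, 1000), iv(100, 900, chrom="chr2")],
            "B": [iv(200, 1100), iv(150, 950, chrom="chr2")],
            "C": [iv(300, 1200), iv(120, 980, chrom="chr2")],
        }
        hs = find_hotspots_multi(amplicons, min_support=3)
        assert [h.interval.chrom for h in hs] == ["chr1", "chr2"]
        assert (hs[0].interval.start, hs[0].interval.end) == (300, 1000)
        assert (hs[1].interval.start, hs[1].interval.end) == (150, 900)
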