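"""Insert-length model, support-count correction, Psi and the
beta-binomial differential test."""

import numpy as np
import pytest

from circexon.config import RunConfig
from circexon.formats_io import AlignmentSegment, ExonIndex, ExonModel
from circexon.psi_quant import (
    InsertLengthDist,
    RouteCoordinates,
    betabinomial_diff_test,
    correct_support_count,
    estimate_insert_distribution,
    estimate_psi,
    linear_psi_from_mrna,
    pair_insert_span,
)


def dist_from(lengths, smooth=0.0, min_pairs=1):
    return InsertLengthDist(lengths, min_pairs=min_pairs, smooth_sigma=smooth)


class TestInsertLengthDist:
    def test_point_mass(self):
        d = dist_from([300] * 50)
        assert d.prob(300) == pytest.approx(1.0)
        assert d.prob(299) == 0.0

    def test_pmf_sums_to_one(self):
        rng = np.random.default_rng(0)
        d = dist_from(list(rng.integers(150, 500, 5000)), smooth=5.0)
        assert d.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_wrap_sum_accumulates_laps(self):
        d = dist_from([200] * 10 + [500] * 10 + [800] * 10)
        assert d.wrap_prob_sum(200, 300) == pytest.approx(1.0)
        assert d.wrap_prob_sum(200, 600) == pytest.approx(2 / 3)

    def test_wrap_vector_matches_scalar(self):
        rng = np.random.default_rng(1)
        d = dist_from(list(rng.integers(100, 700, 3000)), smooth=3.0)
        for J in (211, 350, 799):
            vec = d.wrap_prob_vector(J)
            for K in (1, 57, J // 2, J):
                assert vec[K % J] == pytest.approx(d.wrap_prob_sum(K, J), abs=1e-12)

    def test_below_min_pairs_unusable(self):
        assert not dist_from([300] * 10, min_pairs=1000).usable


def mate(rid, m, pos, length, strand, chrom="chr1", rl=100):
    qs, qe = 0, length
    return AlignmentSegment(rid, m, chrom, pos, strand,
                            (("M", length), ("S", rl - length)) if strand == "+"
                            else (("S", rl - length), ("M", length)),
                            qs, qe, 60, rl)


class TestEstimateInsertDistribution:
    def _index(self):
        # g1: one 2000 bp constitutive exon; g2: exon differs between transcripts
        return ExonIndex(
            [
                ExonModel("chr1", 1001, 3000, "+", "g1", "t1"),
                ExonModel("chr1", 5000, 6500, "+", "g2", "t1"),
                ExonModel("chr1", 5000, 6400, "+", "g2", "t2"),
            ]
        )

    def _pair(self, rid, start, span):
        return [
            mate(rid, 1, start, 100, "+"),
            mate(rid, 2, start + span - 100, 100, "-"),
        ]

    def test_spans_collected_from_constitutive_long_exon(self):
        aln = {f"p{i}": self._pair(f"p{i}", 1100 + i, 300) for i in range(30)}
        cfg = RunConfig(min_insert_pairs=10, insert_smooth_sigma=0.0)
        d = estimate_insert_distribution(aln, self._index(), cfg)
        assert d.n == 30
        assert d.prob(300) == pytest.approx(1.0)

    def test_alternatively_spliced_exon_excluded(self):
        aln = {"q": [mate("q", 1, 5100, 100, "+"), mate("q", 2, 5300, 100, "-")]}
        cfg = RunConfig(min_insert_pairs=1, insert_smooth_sigma=0.0)
        with pytest.warns(UserWarning, match="usable"):
            d = estimate_insert_distribution(aln, self._index(), cfg)
        assert d.n == 0

    def test_pair_outside_long_exon_excluded(self):
        aln = {"q": self._pair("q", 2900, 300)}  # runs past the exon end
        cfg = RunConfig(min_insert_pairs=1, insert_smooth_sigma=0.0)
        with pytest.warns(UserWarning):
            d = estimate_insert_distribution(aln, self._index(), cfg)
        assert d.n == 0


class TestCorrectSupportCount:
    def test_single_term_sum_inflates_by_inverse_probability(self):
        # all mass at K = 300; K + J beyond support -> sum = P(K)
        d = dist_from([300] * 60 + [250] * 40)
        c = correct_support_count(5, 0, 300, None, 400, d)
        assert c == pytest.approx(2 * 5 / 0.6)
        assert c >= 5  # divisor <= 1

    def test_matches_brute_force_wrap_summation(self):
        rng = np.random.default_rng(3)
        d = dist_from(list(rng.integers(100, 900, 4000)), smooth=0.0)
        J, K = 150, 120
        brute = sum(d.prob(K + i * J) for i in range(0, 1000))
        got = correct_support_count(4, 4, K, K, J, d, dominance_ratio=10)
        assert got == pytest.approx(2 * 4 / brute)

    def test_zero_minor_strand_uses_dominant_branch(self):
        d = dist_from([300] * 100)
        assert correct_support_count(9, 0, 300, None, 500, d) == pytest.approx(
            2 * 9 / d.wrap_prob_sum(300, 500)
        )

    def test_unusable_probability_returns_none(self):
        d = dist_from([300] * 100)
        assert correct_support_count(0, 0, None, None, 500, d) is None


def plus_coords():
    return RouteCoordinates([(101, 200), (301, 400)], "+", "chr1")


class TestPairInsertSpan:
    def _segments(self, rl=50):
        # fwd read starts at transcript offset 10 (genomic 111),
        # rev read ends at transcript offset 149 (genomic 350)
        return [
            mate("p", 1, 111, rl, "+", rl=rl),
            mate("p", 2, 301, rl, "-", rl=rl),
        ]

    def test_span_in_transcript_space(self):
        coords = plus_coords()
        # rev read covers genomic [301,350] = offsets [100,149]
        K = pair_insert_span(self._segments(), coords)
        assert K == 149 - 10 + 1

    def test_minus_strand_isoform(self):
        coords = RouteCoordinates([(101, 200), (301, 400)], "-", "chr1")
        segs = [
            mate("p", 1, 351, 50, "-", rl=50),  # offsets 0..49 from genomic 400
            mate("p", 2, 151, 50, "+", rl=50),  # rev read, ends at offset 149
        ]
        assert pair_insert_span(segs, coords) == 150

    def test_missing_mate_returns_none(self):
        assert pair_insert_span(self._segments()[:1], plus_coords()) is None


class TestEstimatePsi:
    def _obs(self, n, K=300):
        return [("fwd", K)] * n

    def test_no_exclusion_reads_gives_psi_one(self):
        est = estimate_psi("c", "ES", (300, 400), self._obs(10), self._obs(10),
                           [], None, None, None)
        assert est.psi_raw == 1.0

    def test_no_inclusion_reads_gives_psi_zero(self):
        est = estimate_psi("c", "ES", (300, 400), [], [], self._obs(7),
                           None, None, None)
        assert est.psi_raw == 0.0

    def test_es_ratio_counts_exclusion_twice(self):
        est = estimate_psi("c", "ES", (300, 400), self._obs(3), self._obs(3),
                           self._obs(3), None, None, None)
        assert est.psi_raw == pytest.approx(6 / 12)

    def test_alt_site_ratio_is_one_sided(self):
        est = estimate_psi("c", "A5SS", (300, 400), self._obs(3), [],
                           self._obs(1), None, None, None)
        assert est.psi_raw == pytest.approx(0.75)

    def test_all_zero_counts_suppressed(self):
        assert estimate_psi("c", "ES", (300, 400), [], [], [], None, None, None) is None

    def test_nested_event_not_corrected(self):
        d = dist_from([300] * 2000, min_pairs=1)
        est = estimate_psi("c", "ES", (300, 400), self._obs(3), self._obs(3),
                           self._obs(3), d, 500, 400, nested=True)
        assert est.psi_corrected is None
        assert not est.correction_applied

    def test_corrected_psi_stays_in_unit_interval(self):
        d = dist_from([300] * 500 + [650] * 500, min_pairs=1)
        est = estimate_psi("c", "ES", (300, 400), self._obs(4), self._obs(2, 650),
                           self._obs(5, 280), d, 700, 400)
        assert est.correction_applied
        assert 0.0 <= est.psi_corrected <= 1.0


class TestLinearPsi:
    SUP = {
        ("chr1", 200, 300): {"a", "b", "c"},
        ("chr1", 400, 500): {"d", "e", "f"},
        ("chr1", 200, 500): set(),
    }

    def test_constitutive_exon_is_one(self):
        psi = linear_psi_from_mrna(self.SUP, "chr1", [(200, 300), (400, 500)],
                                   [(200, 500)])
        assert psi == 1.0

    def test_absent_exon_is_zero(self):
        psi = linear_psi_from_mrna({}, "chr1", [(200, 300)], [(200, 500)],
                                   covered=False)
        assert psi == 0.0

    def test_half_included_exon(self):
        # 3 reads per inclusion site vs 3 skipping reads (counted twice in
        # the denominator): Psi = (3+3)/(3+3+6) = 0.5
        sup = dict(self.SUP)
        sup[("chr1", 200, 500)] = {"g", "h", "i"}
        psi = linear_psi_from_mrna(sup, "chr1", [(200, 300), (400, 500)],
                                   [(200, 500)])
        assert psi == pytest.approx(0.5)

    def test_no_junction_coverage_is_none(self):
        assert linear_psi_from_mrna({}, "chr1", [(200, 300)], [(200, 500)]) is None


class TestBetaBinomialTest:
    def test_identical_proportions_accept_null(self):
        stat, p = betabinomial_diff_test([40, 38], [40, 41], [39, 40], [41, 40])
        assert p > 0.5

    def test_fully_separated_proportions_reject(self):
        stat, p = betabinomial_diff_test(50, 0, 0, 50)
        assert p < 1e-6

    def test_degenerate_all_in_both_conditions(self):
        assert betabinomial_diff_test(30, 0, 20, 0) == (0.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            betabinomial_diff_test(-1, 5, 3, 3)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            betabinomial_diff_test(0, 0, 5, 5)
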