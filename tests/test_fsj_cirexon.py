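"""FSJ detection, signal refinement and cirexon candidate pairing."""

import itertools

import pytest

from circexon.bsj_support import BsjReadPair
from circexon.config import RunConfig
from circexon.formats_io import AlignmentSegment, CircEntry, ExonIndex, ExonModel
from circexon.fsj_cirexon import (
    Cirexon,
    FsjCandidate,
    classify_annotation,
    cluster_and_refine,
    detect_fsj_candidates,
    pair_cirexons,
)
from circexon.splice import fsj_signal_ok


def seg(rid, mate, pos, qs, qe, chrom="toy", strand="+", mapq=60):
    m = qe - qs
    return AlignmentSegment(
        rid, mate, chrom, pos, strand,
        (("S", qs), ("M", m), ("S", 100 - qe)), qs, qe, mapq, 100,
    )


def pair(rid, segs, circ_id="toy:21|220"):
    return BsjReadPair(circ_id, rid, segs)


CIRC = CircEntry("toy:21|220", "toy", 21, 220, "+", {"a", "b", "c"})


class TestDetect:
    def test_split_read_votes_donor_and_acceptor(self):
        p = pair("a", [seg("a", 1, 1000, 0, 50, chrom="chr1"),
                       seg("a", 1, 2000, 50, 100, chrom="chr1")])
        circ = CircEntry("chr1:900|2100", "chr1", 900, 2100, "+", {"a"})
        (v,) = detect_fsj_candidates([p], circ)
        assert (v.donor, v.acceptor) == (1049, 2000)

    def test_opposite_strand_segments_give_no_candidate(self):
        p = pair("a", [seg("a", 1, 1000, 0, 50),
                       seg("a", 1, 2000, 50, 100, strand="-")])
        assert detect_fsj_candidates([p], None) == []

    def test_candidate_outside_circle_discarded(self):
        p = pair("a", [seg("a", 1, 1000, 0, 50, chrom="chr1"),
                       seg("a", 1, 5000, 50, 100, chrom="chr1")])
        circ = CircEntry("chr1:900|2100", "chr1", 900, 2100, "+", {"a"})
        assert detect_fsj_candidates([p], circ) == []

    def test_minus_strand_split(self):
        # transcript runs right-to-left: query-later segment maps upstream
        p = pair("a", [seg("a", 1, 2000, 0, 50, chrom="chr1", strand="-"),
                       seg("a", 1, 1000, 50, 100, chrom="chr1", strand="-")])
        (v,) = detect_fsj_candidates([p], None)
        assert (v.donor, v.acceptor) == (1049, 2000)


class TestClusterAndRefine:
    def _votes(self, circ=CIRC):
        # both reads split across intron 1 of the toy contig: true junction
        # donor=60, acceptor=101; one alignment is off by one base
        pairs = [
            pair("a", [seg("a", 1, 21, 0, 40), seg("a", 1, 101, 40, 80)]),
            pair("b", [seg("b", 2, 22, 0, 40), seg("b", 2, 102, 40, 80)]),
        ]
        return detect_fsj_candidates(pairs, circ)

    def test_cluster_refines_to_splice_signal(self, toy_genome):
        (f,) = cluster_and_refine(self._votes(), toy_genome)
        assert (f.donor, f.acceptor, f.signal, f.refined) == (60, 101, "GT-AG", True)
        assert f.support == 2

    def test_refined_placement_is_minimal_shift(self, toy_genome):
        """Brute-force oracle: among all signal placements in the window,
        the chosen one has the smallest total shift from the estimates."""
        (f,) = cluster_and_refine(self._votes(), toy_genome)
        d_est, a_est = 60, 101  # median of the two votes
        best = min(
            (
                (abs(dd) + abs(da), d_est + dd, a_est + da)
                for dd in range(-10, 11)
                for da in range(-10, 11)
                if fsj_signal_ok(toy_genome, "toy", d_est + dd, a_est + da, "+")
            ),
        )
        assert (f.donor, f.acceptor) == (best[1], best[2])

    def test_refined_junction_carries_canonical_signal(self, toy_genome):
        for f in cluster_and_refine(self._votes(), toy_genome):
            orientation = "+" if f.signal == "GT-AG" else "-"
            assert fsj_signal_ok(toy_genome, f.chrom, f.donor, f.acceptor, orientation)

    def test_single_read_without_signal_dropped(self):
        # signal-free contig: no GT/AG exists anywhere in the window
        from circexon.formats_io import Genome

        blank = Genome({"toy": "A" * 400})
        p = pair("a", [seg("a", 1, 101, 0, 15), seg("a", 1, 121, 15, 80)])
        votes = detect_fsj_candidates([p], CIRC)
        assert cluster_and_refine(votes, blank) == []

    def test_unrefined_cluster_kept_at_min_support(self):
        from circexon.formats_io import Genome

        blank = Genome({"toy": "A" * 400})
        pairs = [
            pair(r, [seg(r, 1, 101, 0, 15), seg(r, 1, 121, 15, 80)])
            for r in ("a", "b", "c")
        ]
        votes = detect_fsj_candidates(pairs, CIRC)
        (f,) = cluster_and_refine(votes, blank)
        assert (f.signal, f.refined, f.support) == ("none", False, 3)

    def test_support_counts_distinct_read_pairs(self, toy_genome):
        pairs = [
            pair("a", [seg("a", 1, 21, 0, 40), seg("a", 1, 101, 40, 80),
                       seg("a", 2, 22, 0, 40), seg("a", 2, 102, 40, 80)]),
            pair("b", [seg("b", 2, 21, 0, 40), seg("b", 2, 101, 40, 80)]),
        ]
        votes = detect_fsj_candidates(pairs, CIRC)
        (f,) = cluster_and_refine(votes, toy_genome)
        assert f.support == 2  # pair 'a' votes twice but counts once


def fsj(donor, acceptor, support=2, chrom="chr1"):
    reads = {f"r{donor}.{acceptor}.{i}": (1, "+") for i in range(support)}
    return FsjCandidate(chrom, donor, acceptor, "GT-AG", True, reads)


class TestPairCirexons:
    CIRC = CircEntry("chr1:100|900", "chr1", 100, 900, "+", {"x", "y"})

    def intervals(self, fsjs):
        return sorted(c.interval for c in pair_cirexons(fsjs, self.CIRC))

    def test_single_fsj_yields_two_terminal_cirexons(self):
        assert self.intervals([fsj(300, 600)]) == [(100, 300), (600, 900)]

    def test_no_fsjs_yield_mono_exon_candidate(self):
        assert self.intervals([]) == [(100, 900)]

    def test_alternative_acceptors_both_retained(self):
        got = self.intervals([fsj(300, 600), fsj(300, 650)])
        assert (600, 900) in got and (650, 900) in got

    def test_enumeration_matches_brute_force(self):
        """Oracle: all acceptor x donor pairs minus those containing a
        complete FSJ."""
        fsjs = [fsj(300, 600), fsj(300, 650), fsj(700, 850)]
        acceptors = {100, 600, 650, 850}
        donors = {300, 700, 900}
        expect = sorted(
            (a, d)
            for a, d in itertools.product(acceptors, donors)
            if a <= d
            and not any(a <= f.donor and f.acceptor <= d for f in fsjs)
        )
        assert self.intervals(fsjs) == expect

    def test_overlong_candidate_deferred(self):
        circ = CircEntry("chr1:100|30000", "chr1", 100, 30000, "+", {"x"})
        (cx,) = pair_cirexons([], circ)
        assert cx.deferred


class TestClassifyAnnotation:
    @pytest.fixture()
    def index(self):
        return ExonIndex(
            [
                ExonModel("chr1", 100, 300, "+", "g", "t1"),
                ExonModel("chr1", 600, 900, "+", "g", "t1"),
            ]
        )

    def test_exact_exon_match(self, index):
        cx = Cirexon("chr1", 100, 300)
        assert classify_annotation(cx, index) == "annotated-exon"
        assert not cx.variant

    def test_intronic_fragment_is_icf(self, index):
        cx = Cirexon("chr1", 400, 450)
        assert classify_annotation(cx, index) == "ICF"

    def test_overlapping_mismatch_flags_variant(self, index):
        cx = Cirexon("chr1", 150, 300)
        assert classify_annotation(cx, index) == "annotated-exon"
        assert cx.variant

    def test_without_annotation_class_is_unknown(self):
        cx = Cirexon("chr1", 100, 300)
        assert classify_annotation(cx, None) == "ICF-unknown"

    def test_tolerance_of_two_bases(self, index):
        cx = Cirexon("chr1", 102, 298)
        assert classify_annotation(cx, index) == "annotated-exon"
        assert not cx.variant
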