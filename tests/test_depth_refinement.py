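"""Depth profiles, the boundary discontinuity test, and candidate rescue."""

import numpy as np
import pytest

from circexon.config import RunConfig
from circexon.depth_refinement import (
    DepthIndex,
    DepthProfile,
    accept_or_split,
    compute_depth_profile,
    rescue_internal_cirexons,
)
from circexon.depth_refinement import test_depth_discontinuity as depth_discontinuity
from circexon.formats_io import AlignmentSegment
from circexon.fsj_cirexon import Cirexon, FsjCandidate


def seg(rid, pos, length=50, chrom="chr1", mate=1, mapq=60):
    return AlignmentSegment(
        rid, mate, chrom, pos, "+", (("M", length),), 0, length, mapq, length
    )


class TestDepthProfile:
    def test_no_reads_gives_zero_profile(self):
        prof = compute_depth_profile([], "chr1", 100, 199)
        assert prof.depth.sum() == 0

    def test_single_read_covers_its_span(self):
        prof = compute_depth_profile([seg("a", 100)], "chr1", 50, 249)
        assert prof.at(100) == 1 and prof.at(149) == 1
        assert prof.at(99) == 0 and prof.at(150) == 0

    def test_overlap_counts_twice(self):
        prof = compute_depth_profile([seg("a", 100), seg("b", 120)], "chr1", 90, 200)
        assert prof.at(130) == 2 and prof.at(110) == 1

    def test_mapq_filter(self):
        prof = compute_depth_profile([seg("a", 100, mapq=5)], "chr1", 90, 200, min_mapq=10)
        assert prof.depth.sum() == 0

    def test_invalid_region_raises(self):
        with pytest.raises(ValueError):
            compute_depth_profile([], "chr1", 200, 100)


def profile_from(values, start=1000):
    return DepthProfile("chr1", start, start + len(values) - 1, np.asarray(values))


class TestDiscontinuity:
    def test_full_separation_is_extreme(self):
        prof = profile_from([30] * 50 + [0] * 50)
        U, p, direction = depth_discontinuity(prof, 1050, flank=50)
        assert U == 50 * 50  # all left ranks above all right ranks
        assert p < 1e-6
        assert direction == "drop"

    def test_identical_windows_are_null(self):
        prof = profile_from([7] * 100)
        U, p, direction = depth_discontinuity(prof, 1050, flank=50)
        assert U == 50 * 50 / 2
        assert p == 1.0
        assert direction == "none"

    def test_rise_direction(self):
        prof = profile_from([0] * 50 + [30] * 50)
        _, p, direction = depth_discontinuity(prof, 1050, flank=50)
        assert p < 1e-6 and direction == "rise"

    def test_uncovered_flank_raises(self):
        prof = profile_from([1] * 60)
        with pytest.raises(ValueError):
            depth_discontinuity(prof, 1005, flank=50)

    def test_type_i_error_near_alpha(self):
        """Homogeneous Poisson coverage: rejection rate ~ alpha (seeded)."""
        rng = np.random.default_rng(11)
        reps, rej = 400, 0
        for _ in range(reps):
            prof = profile_from(rng.poisson(30, 100))
            _, p, _ = depth_discontinuity(prof, 1050, flank=50)
            rej += p < 0.05
        assert 0.02 <= rej / reps <= 0.08


def make_depth_index(segments, length=5000):
    return DepthIndex(segments, {"chr1": length}, 0)


def tiling_segments(start, end, rid_prefix="t", step=40, length=50):
    out = []
    for i, pos in enumerate(range(start, end - length + 2, step)):
        out.append(seg(f"{rid_prefix}{i}", pos, length))
    out.append(seg(f"{rid_prefix}z", end - length + 1, length))
    return out


class TestAcceptOrSplit:
    def test_fully_tiled_candidate_accepted(self):
        cand = Cirexon("chr1", 1000, 1400, evidence="fsj-paired")
        bsj = tiling_segments(1000, 1400)
        out = accept_or_split(cand, bsj, make_depth_index(bsj), [], RunConfig())
        assert [c.interval for c in out] == [(1000, 1400)]
        assert out[0].evidence == "fsj-paired"

    def test_uniform_untiled_candidate_accepted(self):
        cand = Cirexon("chr1", 1000, 1079, evidence="terminal")
        cover = tiling_segments(900, 1200, "x", step=10)  # non-BSJ coverage
        out = accept_or_split(cand, [], make_depth_index(cover), [], RunConfig())
        assert [c.interval for c in out] == [(1000, 1079)]

    def test_merged_exon_intron_exon_rejected_and_rescued(self):
        """Exons [1000,1200] and [1500,1700] with an empty intron: the merged
        candidate fails the depth test and rescue splits it at the non-BSJ
        FSJ.  Spliced coverage is flat across each exon (reads crossing an
        exon end are split, so their exonic blocks reach the boundary)."""
        cand = Cirexon("chr1", 1000, 1700, evidence="terminal")
        cover = [seg(f"a{i}", 1000, 201) for i in range(5)] + [
            seg(f"b{i}", 1500, 201) for i in range(5)
        ]
        bsj = [seg("p1", 1000, 201), seg("p2", 1500, 201)]
        f = FsjCandidate("chr1", 1200, 1500, "GT-AG", True, {"n1": (1, "+")})
        out = accept_or_split(cand, bsj, make_depth_index(cover + bsj), [f], RunConfig())
        assert sorted(c.interval for c in out) == [(1000, 1200), (1500, 1700)]
        assert all(c.evidence == "rescued" for c in out)

    def test_rescue_failure_reports_unresolved(self):
        cand = Cirexon("chr1", 1000, 1700, evidence="terminal")
        cover = tiling_segments(900, 1200, "a", step=10) + tiling_segments(
            1500, 1800, "b", step=10
        )
        out = accept_or_split(cand, [], make_depth_index(cover), [], RunConfig())
        assert [c.evidence for c in out] == ["unresolved"]
        assert out[0].interval == (1000, 1700)


class TestRescue:
    def _reject(self):
        return Cirexon("chr1", 1000, 1700, evidence="terminal")

    def test_unambiguous_fsj_splits_candidate(self):
        cover = [seg(f"a{i}", 1000, 201) for i in range(5)] + [
            seg(f"b{i}", 1500, 201) for i in range(5)
        ]
        f = FsjCandidate("chr1", 1200, 1500, "GT-AG", True, {"n1": (1, "+")})
        out = rescue_internal_cirexons(
            self._reject(), [], make_depth_index(cover), [f], RunConfig()
        )
        assert sorted(c.interval for c in out) == [(1000, 1200), (1500, 1700)]

    def test_competitor_sharing_donor_excludes_both(self):
        f1 = FsjCandidate("chr1", 1200, 1500, "GT-AG", True, {"n1": (1, "+")})
        f2 = FsjCandidate("chr1", 1200, 1550, "GT-AG", True, {"n2": (1, "+")})
        out = rescue_internal_cirexons(
            self._reject(), [], make_depth_index([]), [f1, f2], RunConfig()
        )
        assert out == []

    def test_rescued_cirexons_stay_inside_parent(self):
        cover = tiling_segments(900, 1800, "c", step=10)
        fsjs = [
            FsjCandidate("chr1", 1100, 1260, "GT-AG", True, {"n1": (1, "+")}),
            FsjCandidate("chr1", 1400, 1620, "GT-AG", True, {"n2": (1, "+")}),
        ]
        out = rescue_internal_cirexons(
            self._reject(), [], make_depth_index(cover), fsjs, RunConfig()
        )
        parent = self._reject()
        for c in out:
            assert parent.start <= c.start <= c.end <= parent.end
            assert c.parent == parent.interval

    def test_fsj_outside_candidate_ignored(self):
        f = FsjCandidate("chr1", 800, 1100, "GT-AG", True, {"n1": (1, "+")})
        out = rescue_internal_cirexons(
            self._reject(), [], make_depth_index([]), [f], RunConfig()
        )
        assert out == []


def test_accepted_set_invariant_to_read_order():
    cand = lambda: Cirexon("chr1", 1000, 1400, evidence="terminal")
    bsj = tiling_segments(1000, 1400)
    cfg = RunConfig()
    a = accept_or_split(cand(), bsj, make_depth_index(bsj), [], cfg)
    b = accept_or_split(cand(), bsj[::-1], make_depth_index(bsj[::-1]), [], cfg)
    assert [c.interval for c in a] == [c.interval for c in b]
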