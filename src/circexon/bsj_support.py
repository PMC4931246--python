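"""Back-spliced-junction read support.

Two roles: (i) collect, per circRNA in an upstream caller's list, all local
alignments of its supporting BSJ read pairs; (ii) a minimal de novo BSJ
caller from chiastic split alignments, enough to run the whole pipeline
end-to-end on simulated libraries without an external caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .config import RunConfig
from .formats_io import AlignmentSegment, CircEntry, Genome, make_circ_id
from .splice import refine_junction

__all__ = ["BsjReadPair", "collect_bsj_read_pairs", "call_bsj_minimal", "chiastic_votes"]


@dataclass
class BsjReadPair:
    """All alignment segments of one BSJ-supporting read pair."""

    circ_id: str
    read_id: str
    segments: List[AlignmentSegment]
    single_mate: bool = False

    def mates_present(self) -> Tuple[bool, bool]:
        mates = {s.mate for s in self.segments}
        return (1 in mates, 2 in mates)


def collect_bsj_read_pairs(
    circ_entries: Sequence[CircEntry],
    alignments: Mapping[str, List[AlignmentSegment]],
    min_mapq: int = 0,
) -> Tuple[Dict[str, List[BsjReadPair]], Dict[str, int]]:
    """Gather the listed BSJ read pairs of every circRNA from the alignments.

    ``alignments`` maps read id -> query-sorted segments (see
    :func:`circexon.formats_io.index_alignments`).  Pairs whose read id is
    absent from the alignments are dropped and counted; a circRNA losing more
    than half of its listed pairs triggers a warning (likely a SAM/list
    mismatch).
    """
    pairs: Dict[str, List[BsjReadPair]] = {}
    dropped: Dict[str, int] = {}
    for circ in circ_entries:
        got: List[BsjReadPair] = []
        n_missing = 0
        for rid in sorted(circ.bsj_read_ids):
            segs = [
                s
                for s in alignments.get(rid, [])
                if s.chrom == circ.chrom and s.mapq >= min_mapq
            ]
            if not segs:
                n_missing += 1
                continue
            mates = {s.mate for s in segs}
            got.append(
                BsjReadPair(circ.circ_id, rid, segs, single_mate=len(mates) < 2)
            )
        pairs[circ.circ_id] = got
        dropped[circ.circ_id] = n_missing
        if circ.bsj_count and n_missing > circ.bsj_count / 2:
            warnings.warn(
                f"{circ.circ_id}: {n_missing}/{circ.bsj_count} listed BSJ read "
                "ids missing from the alignments"
            )
    return pairs, dropped


def _neighbour_pairs(segments: Sequence[AlignmentSegment]):
    """Query-order neighbouring segment pairs within each mate."""
    by_mate: Dict[int, List[AlignmentSegment]] = {}
    for s in segments:
        by_mate.setdefault(s.mate, []).append(s)
    for mate in sorted(by_mate):
        segs = sorted(by_mate[mate], key=lambda s: (s.query_start, s.query_end))
        for a, b in zip(segs, segs[1:]):
            yield a, b


def chiastic_votes(
    segments: Sequence[AlignmentSegment],
    max_query_gap: int,
) -> List[Tuple[str, int, int]]:
    """Naive back-splice breakpoints voted by one read's split alignments.

    A vote arises from two query-adjacent segments on the same chromosome and
    strand whose reference order is inverted relative to their query order.
    Returns (chrom, start, end) with start = acceptor, end = donor.
    """
    votes = []
    for a, b in _neighbour_pairs(segments):
        if a.chrom != b.chrom or a.strand != b.strand:
            continue
        if abs(b.query_start - a.query_end) > max_query_gap:
            continue
        if a.strand == "+":
            # read runs genomically forward; inverted order = b upstream of a
            if b.pos < a.pos and b.pos < a.ref_end:
                start, end = b.pos, a.ref_end
                if start < end:
                    votes.append((a.chrom, start, end))
        else:
            # read runs genomically backward; inverted order = b downstream
            if b.ref_end > a.ref_end and a.pos < b.ref_end:
                start, end = a.pos, b.ref_end
                if start < end:
                    votes.append((a.chrom, start, end))
    return votes


def call_bsj_minimal(
    alignments: Mapping[str, List[AlignmentSegment]],
    genome: Genome,
    config: Optional[RunConfig] = None,
) -> List[CircEntry]:
    """Call back-spliced junctions de novo from chiastic split alignments.

    Each chiastic read votes for a breakpoint, refined to the nearest
    canonical back-splice signal (GT/AG on either strand) within
    ``config.bsj_signal_window``; ties resolved by minimal shift, then
    leftmost.  Junctions with at least ``config.min_bsj_support`` distinct
    read pairs are emitted.  The circRNA strand is inferred from the signal
    orientation ('.' when supporting votes disagree).
    """
    cfg = config or RunConfig()
    support: Dict[Tuple[str, int, int], Dict[str, str]] = {}
    for rid in sorted(alignments):
        segs = [s for s in alignments[rid] if s.mapq >= cfg.min_mapq]
        for chrom, start, end in chiastic_votes(segs, cfg.max_query_gap):
            refined = refine_junction(
                genome, chrom, start, end, cfg.bsj_signal_window, kind="bsj"
            )
            if refined is None:
                continue
            r_start, r_end, orientation = refined
            if r_start >= r_end:
                continue
            support.setdefault((chrom, r_start, r_end), {})[rid] = orientation
    out: List[CircEntry] = []
    for (chrom, start, end), reads in sorted(support.items()):
        if len(reads) < cfg.min_bsj_support:
            continue
        orientations = set(reads.values())
        strand = orientations.pop() if len(orientations) == 1 else "."
        out.append(
            CircEntry(
                make_circ_id(chrom, start, end),
                chrom,
                start,
                end,
                strand,
                set(reads),
            )
        )
    return out
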