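"""Forward splice junctions and candidate cirexons from split alignments.

Split alignments of BSJ read pairs are the primary evidence for the internal
structure of a circRNA: each query-adjacent segment pair mapping colinearly
with a reference gap votes for a forward splice junction (FSJ).  Votes are
clustered, refined to canonical splice signals, and FSJ donors/acceptors are
paired into candidate internal exons ("cirexons").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .bsj_support import BsjReadPair, _neighbour_pairs
from .config import RunConfig
from .formats_io import AlignmentSegment, CircEntry, ExonIndex, Genome
from .splice import refine_junction

__all__ = [
    "RawFsj",
    "FsjCandidate",
    "Cirexon",
    "detect_fsj_candidates",
    "detect_fsj_from_reads",
    "cluster_and_refine",
    "pair_cirexons",
    "classify_annotation",
]

_SIGNAL_BY_ORIENTATION = {"+": "GT-AG", "-": "CT-AC"}


@dataclass(frozen=True)
class RawFsj:
    """One read's vote for a forward splice junction (positions estimated)."""

    chrom: str
    donor: int  # last base of the genomically left exon (estimated)
    acceptor: int  # first base of the genomically right exon (estimated)
    slack: int  # unaligned query bases at the junction
    read_id: str
    mate: int
    seg_strand: str


@dataclass
class FsjCandidate:
    """A clustered, optionally signal-refined forward splice junction."""

    chrom: str
    donor: int
    acceptor: int
    signal: str  # 'GT-AG', 'CT-AC' or 'none'
    refined: bool
    support_reads: Dict[str, Tuple[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor - 1:
            raise ValueError("FSJ must splice out at least one base")

    @property
    def support(self) -> int:
        """Distinct supporting read pairs."""
        return len(self.support_reads)

    @property
    def strand(self) -> str:
        if self.signal == "GT-AG":
            return "+"
        if self.signal == "CT-AC":
            return "-"
        return "."


@dataclass
class Cirexon:
    """An internal exon of a circRNA, 1-based inclusive boundaries."""

    chrom: str
    start: int
    end: int
    circ_ids: Set[str] = field(default_factory=set)
    evidence: str = "fsj-paired"  # fsj-paired | terminal | rescued | unresolved
    annotation_class: str = "ICF-unknown"
    support5: int = 0
    support3: int = 0
    deferred: bool = False
    variant: bool = False
    parent: Optional[Tuple[int, int]] = None  # rescue parent candidate

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("cirexon start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


def _colinear_vote(a: AlignmentSegment, b: AlignmentSegment, max_query_gap: int, max_intron: int):
    """Donor/acceptor estimate from a query-adjacent colinear segment pair."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return None
    gap = b.query_start - a.query_end
    if abs(gap) > max_query_gap:
        return None
    if a.strand == "+":
        donor, acceptor = a.ref_end, b.pos
    else:
        donor, acceptor = b.ref_end, a.pos
    intron = acceptor - donor - 1
    if intron < 1 or intron > max_intron:
        return None
    return donor, acceptor, max(gap, 0)


def detect_fsj_candidates(
    bsj_pairs: Sequence[BsjReadPair],
    circ: Optional[CircEntry] = None,
    config: Optional[RunConfig] = None,
) -> List[RawFsj]:
    """Raw FSJ votes from the split alignments of BSJ read pairs.

    Candidates whose boundaries fall outside the hosting circRNA are
    discarded.
    """
    cfg = config or RunConfig()
    out: List[RawFsj] = []
    for pair in bsj_pairs:
        for a, b in _neighbour_pairs(pair.segments):
            vote = _colinear_vote(a, b, cfg.max_query_gap, cfg.max_intron)
            if vote is None:
                continue
            donor, acceptor, slack = vote
            if circ is not None and not (circ.start <= donor and acceptor <= circ.end):
                continue
            out.append(RawFsj(a.chrom, donor, acceptor, slack, pair.read_id, a.mate, a.strand))
    return out


def detect_fsj_from_reads(
    alignments: Dict[str, List[AlignmentSegment]],
    config: Optional[RunConfig] = None,
    min_mapq: Optional[int] = None,
) -> List[RawFsj]:
    """Raw FSJ votes from every read in the alignment index (non-BSJ use)."""
    cfg = config or RunConfig()
    mq = cfg.min_mapq if min_mapq is None else min_mapq
    out: List[RawFsj] = []
    for rid in sorted(alignments):
        segs = [s for s in alignments[rid] if s.mapq >= mq]
        for a, b in _neighbour_pairs(segs):
            vote = _colinear_vote(a, b, cfg.max_query_gap, cfg.max_intron)
            if vote is None:
                continue
            donor, acceptor, slack = vote
            out.append(RawFsj(a.chrom, donor, acceptor, slack, rid, a.mate, a.strand))
    return out


def cluster_and_refine(
    raw: Sequence[RawFsj],
    genome: Genome,
    config: Optional[RunConfig] = None,
    min_refined_support: int = 1,
) -> List[FsjCandidate]:
    """Cluster overlapping FSJ votes and refine them to splice signals.

    Votes whose donor and acceptor estimates both lie within the signal
    window of each other are merged; the merged estimate is refined to the
    canonical signal placement with minimal shift (ties leftmost).  Clusters
    without a signal are kept only with support >= min_unrefined_support.
    """
    cfg = config or RunConfig()
    w = cfg.signal_window
    clusters: List[List[RawFsj]] = []
    for vote in sorted(raw, key=lambda v: (v.chrom, v.donor, v.acceptor, v.read_id, v.mate)):
        placed = False
        for cl in clusters:
            rep = cl[0]
            if (
                vote.chrom == rep.chrom
                and abs(vote.donor - rep.donor) <= w
                and abs(vote.acceptor - rep.acceptor) <= w
            ):
                cl.append(vote)
                placed = True
                break
        if not placed:
            clusters.append([vote])

    refined_map: Dict[Tuple[str, int, int, str], FsjCandidate] = {}
    for cl in clusters:
        chrom = cl[0].chrom
        donors = sorted(v.donor for v in cl)
        acceptors = sorted(v.acceptor for v in cl)
        d_est = donors[len(donors) // 2]
        a_est = acceptors[len(acceptors) // 2]
        support_reads = {}
        for v in cl:
            support_reads.setdefault(v.read_id, (v.mate, v.seg_strand))
        hit = refine_junction(genome, chrom, d_est, a_est, w, kind="fsj")
        if hit is not None:
            donor, acceptor, orientation = hit
            if donor >= acceptor - 1 or len(support_reads) < min_refined_support:
                continue
            key = (chrom, donor, acceptor, orientation)
            if key in refined_map:
                refined_map[key].support_reads.update(support_reads)
            else:
                refined_map[key] = FsjCandidate(
                    chrom, donor, acceptor,
                    _SIGNAL_BY_ORIENTATION[orientation], True, support_reads,
                )
        else:
            if len(support_reads) < cfg.min_unrefined_support or d_est >= a_est - 1:
                continue
            key = (chrom, d_est, a_est, "none")
            if key in refined_map:
                refined_map[key].support_reads.update(support_reads)
            else:
                refined_map[key] = FsjCandidate(chrom, d_est, a_est, "none", False, support_reads)
    return sorted(refined_map.values(), key=lambda f: (f.chrom, f.donor, f.acceptor))


def pair_cirexons(
    fsjs: Sequence[FsjCandidate],
    circ: CircEntry,
    config: Optional[RunConfig] = None,
) -> List[Cirexon]:
    """Pair splice acceptors with downstream donors into candidate cirexons.

    Acceptors are the circle's back-splice start plus every FSJ acceptor;
    donors are every FSJ donor plus the circle's back-splice end.  A candidate
    [a, d] is suppressed when a complete refined FSJ lies wholly inside it
    (that junction splices the interior out, contradicting one continuous
    exon); a bare intervening acceptor or donor (an alternative 5'/3'
    boundary) does not suppress.  Candidates longer than
    ``max_cirexon_candidate`` are emitted but deferred to depth testing.
    """
    cfg = config or RunConfig()
    in_circ = [f for f in fsjs if circ.start <= f.donor and f.acceptor <= circ.end]
    acceptors = {circ.start: None}
    donors = {circ.end: None}
    for f in in_circ:
        acceptors.setdefault(f.acceptor, f)
        donors.setdefault(f.donor, f)
    complete = [
        (f.donor, f.acceptor) for f in in_circ if f.refined
    ]
    out: List[Cirexon] = []
    for a in sorted(acceptors):
        for d in sorted(donors):
            if d < a:
                continue
            if any(a <= fd and fa <= d for fd, fa in complete):
                continue
            sup5 = acceptors[a].support if acceptors[a] is not None else circ.bsj_count
            sup3 = donors[d].support if donors[d] is not None else circ.bsj_count
            evidence = (
                "terminal" if (a == circ.start or d == circ.end) else "fsj-paired"
            )
            out.append(
                Cirexon(
                    circ.chrom,
                    a,
                    d,
                    circ_ids={circ.circ_id},
                    evidence=evidence,
                    support5=sup5,
                    support3=sup3,
                    deferred=(d - a + 1) > cfg.max_cirexon_candidate,
                )
            )
    return out


def classify_annotation(
    cirexon: Cirexon,
    exon_index: Optional[ExonIndex],
    tol: int = 2,
) -> str:
    """Annotate a cirexon against the gene models.

    'annotated-exon' when both boundaries match an annotated exon within
    +-tol bp; 'ICF' (intronic/intergenic circRNA fragment) when it overlaps
    no annotated exon at all; overlapping-but-mismatched cases are
    'annotated-exon' with the variant flag set.  Without annotation the class
    is 'ICF-unknown'.
    """
    if exon_index is None:
        cirexon.annotation_class = "ICF-unknown"
        return cirexon.annotation_class
    hits = exon_index.query(cirexon.chrom, cirexon.start, cirexon.end)
    if not hits:
        cirexon.annotation_class = "ICF"
    elif any(
        abs(h.start - cirexon.start) <= tol and abs(h.end - cirexon.end) <= tol
        for h in hits
    ):
        cirexon.annotation_class = "annotated-exon"
    else:
        cirexon.annotation_class = "annotated-exon"
        cirexon.variant = True
    return cirexon.annotation_class
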