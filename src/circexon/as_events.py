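"""Route construction and alternative-splicing event classification.

Accepted cirexons are traversed along their FSJs to enumerate every route
between the circular-junction acceptor and donor; each route is a potential
circular transcript.  Comparing routes yields the four AS event classes:
exon skipping (ES), alternative 5'/3' splice site (A5SS/A3SS) and intron
retention (IR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .config import RunConfig
from .formats_io import AlignmentSegment, CircEntry
from .fsj_cirexon import Cirexon, FsjCandidate

__all__ = [
    "Route",
    "AsEventGroup",
    "build_routes",
    "classify_as_events",
    "summarize_frequencies",
]


@dataclass
class Route:
    """One possible circular transcript: an ordered chain of cirexons."""

    circ_id: str
    cirexons: List[Cirexon]
    junctions: List[Optional[FsjCandidate]]  # None marks abutting rescue siblings
    truncated: bool = False

    @property
    def circumference(self) -> int:
        """Total exonic length J of the isoform (bases)."""
        return sum(cx.length for cx in self.cirexons)

    @property
    def support_sum(self) -> int:
        """Summed read-pair support of the route's FSJs (shared junctions
        contribute to every route that uses them)."""
        return sum(j.support for j in self.junctions if j is not None)

    def contains(self, interval: Tuple[int, int]) -> bool:
        return any(cx.interval == tuple(interval) for cx in self.cirexons)


@dataclass
class AsEventGroup:
    """A cluster of alternatively spliced cirexons (or a retained intron)."""

    circ_id: str
    event_type: str  # primary label
    labels: Set[str]
    members: List[Tuple[int, int]]
    inclusion_fsjs: List[FsjCandidate] = field(default_factory=list)
    exclusion_fsjs: List[FsjCandidate] = field(default_factory=list)
    nested: bool = False


def build_routes(
    cirexons: Sequence[Cirexon],
    fsjs: Sequence[FsjCandidate],
    circ: CircEntry,
    config: Optional[RunConfig] = None,
) -> List[Route]:
    """Enumerate all cirexon routes from the back-splice acceptor to donor.

    Nodes are cirexons; an edge joins X to Y when an FSJ has donor == X.end
    and acceptor == Y.start, or when X and Y are abutting siblings rescued
    from one parent candidate.  Depth-first enumeration over this DAG, capped
    at ``max_routes`` (remaining routes are dropped and every returned route
    is flagged truncated).  An empty list means no route reaches the
    back-splice donor: the circRNA has an incomplete structure and no AS
    calls are made.
    """
    cfg = config or RunConfig()
    nodes = sorted(
        (cx for cx in cirexons if cx.evidence != "unresolved"),
        key=lambda c: (c.start, c.end),
    )
    edge_map: Dict[int, List[Tuple[int, Optional[FsjCandidate]]]] = {
        i: [] for i in range(len(nodes))
    }
    for i, x in enumerate(nodes):
        for j, y in enumerate(nodes):
            if y.start <= x.end:
                continue
            fsj = next(
                (f for f in fsjs if f.donor == x.end and f.acceptor == y.start),
                None,
            )
            if fsj is not None:
                edge_map[i].append((j, fsj))
            elif (
                y.start == x.end + 1
                and x.parent is not None
                and x.parent == y.parent
            ):
                edge_map[i].append((j, None))

    starts = [i for i, cx in enumerate(nodes) if cx.start == circ.start]
    routes: List[Route] = []
    truncated = False

    def dfs(i: int, chain: List[int], juncs: List[Optional[FsjCandidate]]):
        nonlocal truncated
        if len(routes) >= cfg.max_routes:
            truncated = True
            return
        if nodes[i].end == circ.end:
            routes.append(
                Route(circ.circ_id, [nodes[k] for k in chain], list(juncs))
            )
            return
        for j, fsj in edge_map[i]:
            dfs(j, chain + [j], juncs + [fsj])

    for i in starts:
        dfs(i, [i], [])
    if truncated:
        for r in routes:
            r.truncated = True
    return routes


def _bsj_covers(
    segments: Sequence[AlignmentSegment], chrom: str, start: int, end: int
) -> bool:
    """True when BSJ-pair segments cover every base of [start, end]."""
    if start > end:
        return True
    cov = np.zeros(end - start + 2, dtype=np.int32)
    any_hit = False
    for seg in segments:
        if seg.chrom != chrom:
            continue
        for bs, be in seg.ref_blocks():
            s = max(bs, start) - start
            e = min(be, end) - start
            if s <= e:
                any_hit = True
                cov[s] += 1
                cov[e + 1] -= 1
    return any_hit and bool(np.all(np.cumsum(cov)[:-1] > 0))


def classify_as_events(
    routes: Sequence[Route],
    cirexons: Sequence[Cirexon],
    fsjs: Sequence[FsjCandidate],
    circ: CircEntry,
    bsj_segments: Optional[Sequence[AlignmentSegment]] = None,
) -> List[AsEventGroup]:
    """Type the AS events implied by the routes.

    ES: a cirexon whose two ends lie strictly within the donor and acceptor
    of a supported FSJ (the exclusion junction).  A5SS/A3SS: two route
    cirexons sharing one boundary and spliced differently at the other; which
    side is the donor depends on the strand, so events on strand '.' are
    typed 'A5SS/A3SS-unresolved'.  IR: an FSJ whose intron plus flanking
    cirexons are fully covered by BSJ read pairs (the spliced form coexists
    by construction).  Groups are keyed by their exclusion junction; a
    circRNA hosting more than one group has all groups flagged nested.
    """
    if not routes:
        return []
    route_exons: Dict[Tuple[int, int], Cirexon] = {}
    for r in routes:
        for cx in r.cirexons:
            route_exons.setdefault(cx.interval, cx)

    groups: List[AsEventGroup] = []

    # --- exon skipping, grouped by the skipping junction
    for f in sorted(fsjs, key=lambda f: (f.donor, f.acceptor)):
        skipped = [
            iv
            for iv in sorted(route_exons)
            if f.donor < iv[0] and iv[1] < f.acceptor
        ]
        if not skipped:
            continue
        used = any(
            j is f for r in routes for j in r.junctions if j is not None
        )
        if not used:
            continue
        inclusion = [
            g
            for g in fsjs
            if any(g.acceptor == iv[0] or g.donor == iv[1] for iv in skipped)
        ]
        if not inclusion:
            continue
        group = AsEventGroup(
            circ_id=circ.circ_id,
            event_type="ES",
            labels={"ES"},
            members=skipped,
            inclusion_fsjs=inclusion,
            exclusion_fsjs=[f],
        )
        groups.append(group)

    # --- alternative 5'/3' splice sites between equivalent cirexons
    intervals = sorted(route_exons)
    alt_pairs: List[Tuple[Tuple[int, int], Tuple[int, int], str]] = []
    for i, a in enumerate(intervals):
        for b in intervals[i + 1 :]:
            if a == b:
                continue
            if a[1] == b[1] and a[0] != b[0]:
                side = "left"  # differing genomic-left boundary
            elif a[0] == b[0] and a[1] != b[1]:
                side = "right"
            else:
                continue
            alt_pairs.append((a, b, side))
    for a, b, side in alt_pairs:
        if circ.strand == "+":
            label = "A3SS" if side == "left" else "A5SS"
        elif circ.strand == "-":
            label = "A5SS" if side == "left" else "A3SS"
        else:
            label = "A5SS/A3SS-unresolved"
        host = next(
            (g for g in groups if a in g.members and b in g.members), None
        )
        if host is not None:
            host.labels.add(label)
            continue
        shared = a[0] if side == "right" else a[1]
        varying = (
            [f for f in fsjs if f.acceptor in (a[0], b[0])]
            if side == "left"
            else [f for f in fsjs if f.donor in (a[1], b[1])]
        )
        groups.append(
            AsEventGroup(
                circ_id=circ.circ_id,
                event_type=label,
                labels={label},
                members=[a, b],
                inclusion_fsjs=[
                    f for f in varying if _form_length(f, side) == max(
                        _form_length(g, side) for g in varying
                    )
                ] if varying else [],
                exclusion_fsjs=[
                    f for f in varying if _form_length(f, side) != max(
                        _form_length(g, side) for g in varying
                    )
                ] if varying else [],
            )
        )

    # --- intron retention
    if bsj_segments is not None:
        for f in sorted(fsjs, key=lambda f: (f.donor, f.acceptor)):
            left = next((iv for iv in intervals if iv[1] == f.donor), None)
            right = next((iv for iv in intervals if iv[0] == f.acceptor), None)
            if left is None or right is None:
                continue
            if _bsj_covers(bsj_segments, circ.chrom, left[0], right[1]):
                groups.append(
                    AsEventGroup(
                        circ_id=circ.circ_id,
                        event_type="IR",
                        labels={"IR"},
                        members=[(f.donor + 1, f.acceptor - 1)],
                        inclusion_fsjs=[],
                        exclusion_fsjs=[f],
                    )
                )

    if len(groups) > 1:
        for g in groups:
            g.nested = True
    return groups


def _form_length(f: FsjCandidate, side: str) -> int:
    # Longer exonic form = smaller intron; rank alternatives by -intron size.
    return -(f.acceptor - f.donor)


def summarize_frequencies(
    as_groups: Dict[str, List[AsEventGroup]],
    circ_entries: Sequence[CircEntry],
    min_bsj: int = 20,
) -> Dict[str, float]:
    """Fraction (%) of well-supported circRNAs hosting each AS event type.

    Only circRNAs with at least ``min_bsj`` BSJ read pairs enter the
    denominator.
    """
    eligible = [c for c in circ_entries if c.bsj_count >= min_bsj]
    out: Dict[str, float] = {t: 0.0 for t in ("ES", "A5SS", "A3SS", "IR")}
    if not eligible:
        return out
    for etype in out:
        n = sum(
            1
            for c in eligible
            if any(etype in g.labels for g in as_groups.get(c.circ_id, []))
        )
        out[etype] = 100.0 * n / len(eligible)
    return out
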