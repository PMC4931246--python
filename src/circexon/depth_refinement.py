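"""Depth-based continuity testing and rescue of merged cirexon candidates.

When no BSJ read pair covers an internal FSJ, junction pairing produces a
single candidate spanning exon-intron-exon.  Continuity is decided from BSJ
read-pair tiling and a Mann-Whitney U test on per-base sequencing depth
around putative internal boundaries; rejected candidates are split at FSJs
recovered from non-BSJ reads and re-checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import RunConfig
from .formats_io import AlignmentSegment
from .fsj_cirexon import Cirexon, FsjCandidate

__all__ = [
    "DepthProfile",
    "DepthIndex",
    "compute_depth_profile",
    "test_depth_discontinuity",
    "accept_or_split",
    "rescue_internal_cirexons",
]


@dataclass
class DepthProfile:
    """Per-base coverage over a 1-based inclusive window."""

    chrom: str
    start: int
    end: int
    depth: np.ndarray

    def __post_init__(self) -> None:
        if len(self.depth) != self.end - self.start + 1:
            raise ValueError("depth length must equal window length")

    def at(self, pos: int) -> int:
        return int(self.depth[pos - self.start])

    def window(self, start: int, end: int) -> np.ndarray:
        """Depths over [start, end], clipped to the profile."""
        s = max(start, self.start)
        e = min(end, self.end)
        if s > e:
            return np.empty(0, dtype=self.depth.dtype)
        return self.depth[s - self.start : e - self.start + 1]


class DepthIndex:
    """Whole-chromosome per-base coverage from aligned M/=/X blocks."""

    def __init__(
        self,
        segments: Iterable[AlignmentSegment],
        chrom_lengths: Dict[str, int],
        min_mapq: int = 0,
    ):
        self._depth = {
            chrom: np.zeros(length + 2, dtype=np.int32)
            for chrom, length in chrom_lengths.items()
        }
        for seg in segments:
            if seg.mapq < min_mapq or seg.chrom not in self._depth:
                continue
            arr = self._depth[seg.chrom]
            for s, e in seg.ref_blocks():
                e = min(e, len(arr) - 2)
                if s <= e:
                    arr[s] += 1
                    arr[e + 1] -= 1
        for chrom in self._depth:
            self._depth[chrom] = np.cumsum(self._depth[chrom])[: chrom_lengths[chrom] + 1]

    def profile(self, chrom: str, start: int, end: int) -> DepthProfile:
        arr = self._depth[chrom]
        start = max(start, 1)
        end = min(end, len(arr) - 1)
        if start > end:
            raise ValueError(f"region {chrom}:{start}-{end} outside reference")
        return DepthProfile(chrom, start, end, arr[start : end + 1].copy())


def compute_depth_profile(
    segments: Iterable[AlignmentSegment],
    chrom: str,
    start: int,
    end: int,
    min_mapq: int = 0,
) -> DepthProfile:
    """Per-base coverage of [start, end] counting M/=/X blocks of the given
    segments with mapping quality >= min_mapq."""
    if start < 1 or start > end:
        raise ValueError(f"invalid region {chrom}:{start}-{end}")
    depth = np.zeros(end - start + 2, dtype=np.int32)
    for seg in segments:
        if seg.chrom != chrom or seg.mapq < min_mapq:
            continue
        for bs, be in seg.ref_blocks():
            s = max(bs, start)
            e = min(be, end)
            if s <= e:
                depth[s - start] += 1
                depth[e - start + 1] -= 1
    return DepthProfile(chrom, start, end, np.cumsum(depth)[:-1])


def test_depth_discontinuity(
    profile: DepthProfile,
    boundary: int,
    flank: int = 50,
    mask: Optional[np.ndarray] = None,
) -> Tuple[float, float, str]:
    """Two-sided Mann-Whitney U test on depth left vs right of a boundary.

    Compares per-base depths in [boundary-flank, boundary-1] against
    [boundary, boundary+flank-1].  Exact p for small tie-free samples
    (n <= 20 per side), otherwise normal approximation with tie correction.
    Returns (U, p, direction) with direction 'drop' when depth falls moving
    rightwards across the boundary, 'rise' when it climbs, 'none' otherwise.
    ``mask`` (aligned to the profile) excludes flagged positions, e.g. bases
    of other detected cirexons.
    """
    if boundary - flank < profile.start or boundary + flank - 1 > profile.end:
        raise ValueError("profile does not cover the flanks around the boundary")
    left = profile.window(boundary - flank, boundary - 1).astype(float)
    right = profile.window(boundary, boundary + flank - 1).astype(float)
    if mask is not None:
        lm = mask[boundary - flank - profile.start : boundary - profile.start]
        rm = mask[boundary - profile.start : boundary + flank - profile.start]
        left = left[~lm]
        right = right[~rm]
    if len(left) == 0 or len(right) == 0:
        return (np.nan, 1.0, "none")
    combined = np.concatenate([left, right])
    if np.all(combined == combined[0]):
        return (len(left) * len(right) / 2.0, 1.0, "none")
    small = len(left) <= 20 and len(right) <= 20
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if small and not ties else "asymptotic"
    res = stats.mannwhitneyu(left, right, alternative="two-sided", method=method)
    delta = np.median(left) - np.median(right)
    direction = "drop" if delta > 0 else ("rise" if delta < 0 else "none")
    return (float(res.statistic), float(res.pvalue), direction)


def _bsj_tiled(candidate: Cirexon, bsj_segments: Sequence[AlignmentSegment]) -> bool:
    """True when every base of the candidate is covered by >=1 BSJ-pair segment."""
    length = candidate.length
    cov = np.zeros(length + 1, dtype=np.int32)
    for seg in bsj_segments:
        if seg.chrom != candidate.chrom:
            continue
        for bs, be in seg.ref_blocks():
            s = max(bs, candidate.start) - candidate.start
            e = min(be, candidate.end) - candidate.start
            if s <= e:
                cov[s] += 1
                cov[e + 1] -= 1
    return bool(np.all(np.cumsum(cov)[:-1] > 0))


def _internal_boundaries(
    candidate: Cirexon,
    nonbsj_fsjs: Sequence[FsjCandidate],
    profile: DepthProfile,
) -> List[int]:
    """Positions at which to test for a depth discontinuity.

    Refined non-BSJ FSJ boundaries strictly inside the candidate take
    priority; otherwise the single position with the largest per-base depth
    step is tested.
    """
    positions = []
    for f in nonbsj_fsjs:
        if f.refined and candidate.start <= f.donor and f.acceptor <= candidate.end:
            positions.extend([f.donor + 1, f.acceptor])
    positions = sorted(
        {p for p in positions if candidate.start < p <= candidate.end}
    )
    if positions:
        return positions
    inner = profile.window(candidate.start, candidate.end).astype(np.int64)
    if len(inner) < 2:
        return []
    steps = np.abs(np.diff(inner))
    best = int(np.argmax(steps))
    if steps[best] == 0:
        return []
    return [candidate.start + best + 1]


def accept_or_split(
    candidate: Cirexon,
    bsj_segments: Sequence[AlignmentSegment],
    depth_index: DepthIndex,
    nonbsj_fsjs: Sequence[FsjCandidate],
    config: Optional[RunConfig] = None,
    rescue: bool = True,
    mask: Optional[np.ndarray] = None,
) -> List[Cirexon]:
    """Decide whether a candidate cirexon is continuously included.

    Fully BSJ-tiled candidates are accepted outright (unless deferred for
    excessive length).  Otherwise internal positions are tested for a
    significant depth discontinuity; a significant step rejects continuity
    and triggers rescue of the cirexons hidden inside.  Returns the accepted
    (or rescued / unresolved) cirexons.
    """
    cfg = config or RunConfig()
    if not candidate.deferred and _bsj_tiled(candidate, bsj_segments):
        return [candidate]
    profile = depth_index.profile(
        candidate.chrom, candidate.start - cfg.flank, candidate.end + cfg.flank
    )
    discontinuous = False
    for boundary in _internal_boundaries(candidate, nonbsj_fsjs, profile):
        try:
            _, p, direction = test_depth_discontinuity(profile, boundary, cfg.flank, mask)
        except ValueError:
            continue
        if p < cfg.alpha and direction != "none":
            discontinuous = True
            break
    if not discontinuous:
        return [candidate]
    if not rescue:
        candidate.evidence = "unresolved"
        return [candidate]
    rescued = rescue_internal_cirexons(
        candidate, bsj_segments, depth_index, nonbsj_fsjs, cfg
    )
    if not rescued:
        candidate.evidence = "unresolved"
        return [candidate]
    return rescued


def rescue_internal_cirexons(
    candidate: Cirexon,
    bsj_segments: Sequence[AlignmentSegment],
    depth_index: DepthIndex,
    nonbsj_fsjs: Sequence[FsjCandidate],
    config: Optional[RunConfig] = None,
) -> List[Cirexon]:
    """Split a rejected candidate at FSJs recovered from non-BSJ reads.

    Eligible FSJs are refined, lie wholly inside the candidate, meet the
    rescue support threshold and have no competitor sharing either splice
    site.  Surviving junctions partition the candidate; each sub-cirexon is
    re-checked by depth once more (no second-level rescue).  An empty return
    means the candidate stays unresolved.
    """
    cfg = config or RunConfig()
    inside = [
        f
        for f in nonbsj_fsjs
        if f.refined
        and f.support >= cfg.min_rescue_support
        and candidate.start <= f.donor
        and f.acceptor <= candidate.end
    ]
    survivors = []
    for f in inside:
        competitor = any(
            g is not f and (g.donor == f.donor or g.acceptor == f.acceptor)
            for g in inside
        )
        if not competitor:
            survivors.append(f)
    survivors.sort(key=lambda f: (f.donor, f.acceptor))
    if not survivors:
        return []
    for a, b in zip(survivors, survivors[1:]):
        if a.acceptor > b.donor:  # overlapping splices: ambiguous, give up
            return []
    bounds = [candidate.start]
    for f in survivors:
        bounds.extend([f.donor, f.acceptor])
    bounds.append(candidate.end)
    out: List[Cirexon] = []
    for i in range(0, len(bounds), 2):
        s, e = bounds[i], bounds[i + 1]
        if s > e:
            return []
        sub = Cirexon(
            candidate.chrom,
            s,
            e,
            circ_ids=set(candidate.circ_ids),
            evidence="rescued",
            support5=candidate.support5 if s == candidate.start else 0,
            support3=candidate.support3 if e == candidate.end else 0,
            parent=candidate.interval,
        )
        out.extend(
            accept_or_split(
                sub, bsj_segments, depth_index, [], cfg, rescue=False
            )
        )
    for cx in out:
        if cx.evidence != "unresolved":
            cx.evidence = "rescued"
        cx.parent = candidate.interval
    return out
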