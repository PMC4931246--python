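"""Pipeline orchestration: collect BSJ pairs, detect FSJs and cirexons,
refine by depth, classify AS events and estimate Psi for every circRNA."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .as_events import AsEventGroup, Route, build_routes, classify_as_events, summarize_frequencies
from .bsj_support import collect_bsj_read_pairs
from .config import RunConfig
from .depth_refinement import DepthIndex, accept_or_split
from .formats_io import (
    AlignmentSegment,
    CircEntry,
    ExonIndex,
    Genome,
    write_outputs,
)
from .fsj_cirexon import (
    Cirexon,
    FsjCandidate,
    classify_annotation,
    cluster_and_refine,
    detect_fsj_candidates,
    detect_fsj_from_reads,
    pair_cirexons,
)
from .psi_quant import (
    InsertLengthDist,
    PsiEstimate,
    RouteCoordinates,
    collect_support_observations,
    estimate_insert_distribution,
    estimate_psi,
    junction_context,
)

logger = logging.getLogger("circexon")

__all__ = ["CircResult", "DetectResult", "run_detect", "run_compare"]

_EVIDENCE_RANK = {"fsj-paired": 0, "terminal": 1, "rescued": 2, "unresolved": 3}


@dataclass
class CircResult:
    circ: CircEntry
    fsjs: List[FsjCandidate]
    cirexons: List[Cirexon]
    routes: List[Route]
    events: List[AsEventGroup]
    psi: List[PsiEstimate]
    incomplete: bool = False
    n_dropped_pairs: int = 0


@dataclass
class DetectResult:
    config: RunConfig
    circ_results: Dict[str, CircResult]
    insert_dist: Optional[InsertLengthDist]
    frequencies: Dict[str, float]

    def cirexon_rows(self):
        for cid in sorted(self.circ_results):
            for cx in sorted(
                self.circ_results[cid].cirexons, key=lambda c: (c.start, c.end)
            ):
                yield cid, cx

    def event_rows(self) -> List[Dict[str, object]]:
        rows = []
        for cid in sorted(self.circ_results):
            res = self.circ_results[cid]
            psi_by_member = {(p.event_type, p.member): p for p in res.psi}
            for g in sorted(res.events, key=lambda g: (g.event_type, g.members)):
                for member in g.members:
                    p = psi_by_member.get((g.event_type, tuple(member)))
                    rows.append(
                        {
                            "circ_id": cid,
                            "event_type": g.event_type,
                            "labels": ",".join(sorted(g.labels)),
                            "members": f"{member[0]}-{member[1]}",
                            "c1": p.c1 if p else 0,
                            "c2": p.c2 if p else 0,
                            "c_out": p.c_out if p else 0,
                            "psi_raw": p.psi_raw if p else None,
                            "psi_corrected": (
                                p.psi_corrected if p and p.psi_corrected is not None else None
                            ),
                            "correction_applied": bool(p.correction_applied) if p else False,
                            "nested": g.nested,
                        }
                    )
        return rows

    def psi_frame(self) -> pd.DataFrame:
        rows = []
        for cid in sorted(self.circ_results):
            res = self.circ_results[cid]
            for p in res.psi:
                rows.append(
                    {
                        "circ_id": p.circ_id,
                        "chrom": res.circ.chrom,
                        "event_type": p.event_type,
                        "member_start": p.member[0],
                        "member_end": p.member[1],
                        "c1": p.c1,
                        "c2": p.c2,
                        "c_out": p.c_out,
                        "psi_raw": p.psi_raw,
                        "psi_corrected": p.psi_corrected,
                        "correction_applied": p.correction_applied,
                        "nested": p.nested,
                        "incl_junctions": p.incl_junctions,
                        "excl_junctions": p.excl_junctions,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "circ_id", "chrom", "event_type", "member_start", "member_end",
                "c1", "c2", "c_out", "psi_raw", "psi_corrected",
                "correction_applied", "nested", "incl_junctions", "excl_junctions",
            ],
        )

    def write(self, out_dir: str) -> Dict[str, str]:
        return write_outputs(
            list(self.cirexon_rows()),
            self.event_rows(),
            self.psi_frame(),
            out_dir,
            header=f"circexon config={self.config.to_json()}",
        )


def _junction_string(fsjs: Sequence[FsjCandidate]) -> str:
    return ";".join(f"{f.donor}:{f.acceptor}" for f in fsjs)


def _dedupe(cirexons: Sequence[Cirexon]) -> List[Cirexon]:
    best: Dict[Tuple[int, int], Cirexon] = {}
    for cx in cirexons:
        key = cx.interval
        old = best.get(key)
        if old is None or _EVIDENCE_RANK.get(cx.evidence, 9) < _EVIDENCE_RANK.get(
            old.evidence, 9
        ):
            if old is not None:
                cx.circ_ids |= old.circ_ids
                cx.support5 = max(cx.support5, old.support5)
                cx.support3 = max(cx.support3, old.support3)
            best[key] = cx
        else:
            old.circ_ids |= cx.circ_ids
            old.support5 = max(cx.support5, old.support5)
            old.support3 = max(cx.support3, old.support3)
    return sorted(best.values(), key=lambda c: (c.start, c.end))


def _route_for(routes: Sequence[Route], member: Tuple[int, int], include: bool) -> Optional[Route]:
    """Smallest route containing (or avoiding) the member interval."""
    pool = [r for r in routes if r.contains(member) == include]
    if not pool:
        return None
    return min(pool, key=lambda r: (r.circumference, len(r.cirexons)))


def _readthrough_support(
    bsj_pairs_by_id: Mapping[str, Sequence[AlignmentSegment]],
    chrom: str,
    donor: int,
    acceptor: int,
    overhang: int = 4,
) -> List[str]:
    """Pairs with a contiguous aligned block reading across either
    exon-intron boundary of a putative retained intron."""
    hits = []
    for rid, segs in sorted(bsj_pairs_by_id.items()):
        for seg in segs:
            if seg.chrom != chrom:
                continue
            found = False
            for bs, be in seg.ref_blocks():
                if (bs <= donor - overhang + 1 and donor + overhang <= be) or (
                    bs <= acceptor - overhang and acceptor + overhang - 1 <= be
                ):
                    found = True
                    break
            if found:
                hits.append(rid)
                break
    return hits


def _psi_for_group(
    group: AsEventGroup,
    fsjs: Sequence[FsjCandidate],
    routes: Sequence[Route],
    circ: CircEntry,
    pairs_by_id: Mapping[str, Sequence[AlignmentSegment]],
    dist: Optional[InsertLengthDist],
    cfg: RunConfig,
) -> List[PsiEstimate]:
    out: List[PsiEstimate] = []
    strand = circ.strand
    rl = next(
        (s.read_length for segs in pairs_by_id.values() for s in segs), 100
    )

    if group.event_type == "ES":
        f_out = group.exclusion_fsjs[0]
        for member in group.members:
            f1 = next((f for f in fsjs if f.acceptor == member[0]), None)
            f2 = next((f for f in fsjs if f.donor == member[1]), None)
            r_in = _route_for(routes, member, True)
            r_out = _route_for(routes, member, False)
            coords_in = (
                RouteCoordinates([cx.interval for cx in r_in.cirexons], strand)
                if r_in else None
            )
            coords_out = (
                RouteCoordinates([cx.interval for cx in r_out.cirexons], strand)
                if r_out else None
            )
            obs1 = (
                collect_support_observations(f1, pairs_by_id, coords_in)
                if f1 and coords_in else []
            )
            obs2 = (
                collect_support_observations(f2, pairs_by_id, coords_in)
                if f2 and coords_in else []
            )
            obs_out = (
                collect_support_observations(f_out, pairs_by_id, coords_out)
                if coords_out else [("fwd", None)] * f_out.support
            )
            est = estimate_psi(
                circ.circ_id, "ES", member, obs1, obs2, obs_out, dist,
                coords_in.J if coords_in else None,
                coords_out.J if coords_out else None,
                nested=group.nested, dominance_ratio=cfg.dominance_ratio,
                ctx1=(
                    junction_context(coords_in, f1.donor, f1.acceptor, rl)
                    if f1 and coords_in else None
                ),
                ctx2=(
                    junction_context(coords_in, f2.donor, f2.acceptor, rl)
                    if f2 and coords_in else None
                ),
                ctx_out=(
                    junction_context(coords_out, f_out.donor, f_out.acceptor, rl)
                    if coords_out else None
                ),
            )
            if est is not None:
                est.incl_junctions = _junction_string([f for f in (f1, f2) if f])
                est.excl_junctions = _junction_string([f_out])
                out.append(est)
        return out

    if group.event_type.startswith("A5SS") or group.event_type.startswith("A3SS"):
        members = sorted(group.members, key=lambda m: m[1] - m[0], reverse=True)
        longer, shorter = members[0], members[-1]
        f_in = group.inclusion_fsjs[0] if group.inclusion_fsjs else None
        f_out = group.exclusion_fsjs[0] if group.exclusion_fsjs else None
        if f_in is None or f_out is None:
            return out
        r_in = _route_for(routes, longer, True)
        r_out = _route_for(routes, shorter, True)
        coords_in = (
            RouteCoordinates([cx.interval for cx in r_in.cirexons], strand)
            if r_in else None
        )
        coords_out = (
            RouteCoordinates([cx.interval for cx in r_out.cirexons], strand)
            if r_out else None
        )
        obs1 = (
            collect_support_observations(f_in, pairs_by_id, coords_in)
            if coords_in else []
        )
        obs_out = (
            collect_support_observations(f_out, pairs_by_id, coords_out)
            if coords_out else []
        )
        est = estimate_psi(
            circ.circ_id, group.event_type, longer, obs1, [], obs_out, dist,
            coords_in.J if coords_in else None,
            coords_out.J if coords_out else None,
            nested=group.nested, dominance_ratio=cfg.dominance_ratio,
            ctx1=(
                junction_context(coords_in, f_in.donor, f_in.acceptor, rl)
                if coords_in else None
            ),
            ctx_out=(
                junction_context(coords_out, f_out.donor, f_out.acceptor, rl)
                if coords_out else None
            ),
        )
        if est is not None:
            est.incl_junctions = _junction_string([f_in])
            est.excl_junctions = _junction_string([f_out])
            out.append(est)
        return out

    if group.event_type == "IR":
        f_out = group.exclusion_fsjs[0]
        member = group.members[0]
        inc_ids = _readthrough_support(
            pairs_by_id, circ.chrom, f_out.donor, f_out.acceptor
        )
        obs1 = [("fwd", None) for _ in inc_ids]
        r_out = _route_for(routes, member, False) or (routes[0] if routes else None)
        coords_out = (
            RouteCoordinates([cx.interval for cx in r_out.cirexons], strand)
            if r_out else None
        )
        obs_out = (
            collect_support_observations(f_out, pairs_by_id, coords_out)
            if coords_out else [("fwd", None)] * f_out.support
        )
        est = estimate_psi(
            circ.circ_id, "IR", member, obs1, [], obs_out, dist,
            None, None, nested=group.nested, dominance_ratio=cfg.dominance_ratio,
        )
        if est is not None:
            est.incl_junctions = ""
            est.excl_junctions = _junction_string([f_out])
            out.append(est)
        return out
    return out


def run_detect(
    genome: Genome,
    alignments: Mapping[str, List[AlignmentSegment]],
    circ_entries: Sequence[CircEntry],
    exon_index: Optional[ExonIndex] = None,
    config: Optional[RunConfig] = None,
) -> DetectResult:
    """Full detection: BSJ pair collection -> FSJ -> cirexon -> depth
    refinement -> routes -> AS events -> Psi.

    ``alignments`` maps read id to query-sorted segments; ``circ_entries``
    comes from an upstream caller or :func:`call_bsj_minimal`.  Without
    annotation, cirexons are classed 'ICF-unknown' and Psi stays uncorrected.
    """
    cfg = config or RunConfig()
    chrom_lengths = {c: genome.length(c) for c in genome.chroms()}
    all_segments = [s for segs in alignments.values() for s in segs]
    depth_index = DepthIndex(all_segments, chrom_lengths, cfg.min_mapq)
    logger.info("indexed %d segments from %d reads", len(all_segments), len(alignments))

    global_fsjs = cluster_and_refine(
        detect_fsj_from_reads(alignments, cfg), genome, cfg
    )
    logger.info("global FSJ candidates: %d", len(global_fsjs))

    insert_dist = (
        estimate_insert_distribution(alignments, exon_index, cfg)
        if exon_index is not None
        else None
    )
    pairs_map, dropped = collect_bsj_read_pairs(circ_entries, alignments, cfg.min_mapq)

    circ_results: Dict[str, CircResult] = {}
    for circ in sorted(circ_entries, key=lambda c: (c.chrom, c.start, c.end)):
        pairs = pairs_map.get(circ.circ_id, [])
        pairs_by_id = {p.read_id: p.segments for p in pairs}
        bsj_segments = [s for p in pairs for s in p.segments]
        bsj_ids = set(pairs_by_id)

        raw = detect_fsj_candidates(pairs, circ, cfg)
        fsjs = cluster_and_refine(raw, genome, cfg)
        candidates = pair_cirexons(fsjs, circ, cfg)

        nonbsj: List[FsjCandidate] = []
        for f in global_fsjs:
            if not (circ.start <= f.donor and f.acceptor <= circ.end):
                continue
            kept = {
                rid: v for rid, v in f.support_reads.items() if rid not in bsj_ids
            }
            if len(kept) >= cfg.min_rescue_support:
                nonbsj.append(
                    FsjCandidate(f.chrom, f.donor, f.acceptor, f.signal, f.refined, kept)
                )

        accepted: List[Cirexon] = []
        for cand in candidates:
            accepted.extend(
                accept_or_split(cand, bsj_segments, depth_index, nonbsj, cfg)
            )
        cirexons = _dedupe(accepted)
        for cx in cirexons:
            classify_annotation(cx, exon_index, cfg.boundary_tol)

        ends = {cx.end for cx in cirexons}
        starts = {cx.start for cx in cirexons}
        route_fsjs = list(fsjs) + [
            f
            for f in nonbsj
            if f.donor in ends and f.acceptor in starts
            and not any(g.donor == f.donor and g.acceptor == f.acceptor for g in fsjs)
        ]
        routes = build_routes(cirexons, route_fsjs, circ, cfg)
        incomplete = not routes
        events = classify_as_events(routes, cirexons, fsjs, circ, bsj_segments)
        psi: List[PsiEstimate] = []
        for g in events:
            psi.extend(
                _psi_for_group(g, fsjs, routes, circ, pairs_by_id, insert_dist, cfg)
            )
        circ_results[circ.circ_id] = CircResult(
            circ, fsjs, cirexons, routes, events, psi, incomplete,
            dropped.get(circ.circ_id, 0),
        )

    frequencies = summarize_frequencies(
        {cid: r.events for cid, r in circ_results.items()},
        list(circ_entries),
        cfg.min_bsj_cutoff,
    )
    logger.info(
        "detection finished: %d circRNAs, %d cirexons, %d AS groups",
        len(circ_results),
        sum(len(r.cirexons) for r in circ_results.values()),
        sum(len(r.events) for r in circ_results.values()),
    )
    return DetectResult(cfg, circ_results, insert_dist, frequencies)


def run_compare(
    psi_table: pd.DataFrame,
    mrna_alignments: Mapping[str, List[AlignmentSegment]],
    genome: Genome,
    config: Optional[RunConfig] = None,
    delta_flag: float = 0.4,
) -> pd.DataFrame:
    """Differential inclusion of skipped cirexons: circRNA vs mRNA.

    mRNA Psi uses the same junction-ratio criteria computed from all poly(A)+
    reads (no BSJ anchoring, no correction); exons constitutive or absent in
    mRNA get Psi 1 or 0.  Each shared event is tested with the beta-binomial
    likelihood-ratio test; raw p and Benjamini-Hochberg FDR are reported and
    |dPsi| > ``delta_flag`` is flagged.
    """
    from statsmodels.stats.multitest import multipletests

    from .psi_quant import betabinomial_diff_test

    cfg = config or RunConfig()
    mrna_fsjs = cluster_and_refine(
        detect_fsj_from_reads(mrna_alignments, cfg), genome, cfg
    )
    support = {
        (f.chrom, f.donor, f.acceptor): set(f.support_reads) for f in mrna_fsjs
    }
    chrom_lengths = {c: genome.length(c) for c in genome.chroms()}
    mrna_depth = DepthIndex(
        (s for segs in mrna_alignments.values() for s in segs),
        chrom_lengths,
        cfg.min_mapq,
    )

    def parse_junctions(text) -> List[Tuple[int, int]]:
        if not isinstance(text, str) or not text:
            return []
        return [tuple(map(int, t.split(":"))) for t in text.split(";")]

    rows = []
    for row in psi_table.itertuples(index=False):
        incl = parse_junctions(row.incl_junctions)
        excl = parse_junctions(row.excl_junctions)
        if not excl:
            continue
        chrom = row.chrom
        m_in = sum(len(support.get((chrom, d, a), ())) for d, a in incl)
        m_out = sum(len(support.get((chrom, d, a), ())) for d, a in excl)
        if m_in + m_out > 0:
            psi_mrna = (
                m_in / (m_in + 2.0 * m_out)
                if len(incl) >= 2
                else m_in / (m_in + float(m_out))
            )
        else:
            prof = mrna_depth.profile(chrom, int(row.member_start), int(row.member_end))
            psi_mrna = 1.0 if prof.depth.mean() >= 1.0 else 0.0
        psi_circ = (
            row.psi_corrected
            if row.psi_corrected is not None and not pd.isna(row.psi_corrected)
            else row.psi_raw
        )
        c_in = int(row.c1) + int(row.c2)
        c_out = 2 * int(row.c_out) if len(incl) >= 2 else int(row.c_out)
        mm_out = 2 * m_out if len(incl) >= 2 else m_out
        if c_in + c_out == 0 or m_in + mm_out == 0:
            stat, p = float("nan"), float("nan")
        else:
            stat, p = betabinomial_diff_test(c_in, c_out, m_in, mm_out)
        rows.append(
            {
                "circ_id": row.circ_id,
                "event_type": row.event_type,
                "member_start": row.member_start,
                "member_end": row.member_end,
                "psi_circ": psi_circ,
                "psi_mrna": psi_mrna,
                "delta_psi": (
                    psi_circ - psi_mrna if psi_circ is not None else float("nan")
                ),
                "lrt_stat": stat,
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "circ_id", "event_type", "member_start", "member_end",
            "psi_circ", "psi_mrna", "delta_psi", "lrt_stat", "p_value",
        ],
    )
    if len(df):
        valid = df["p_value"].notna()
        fdr = pd.Series(np.nan, index=df.index)
        if valid.any():
            fdr[valid] = multipletests(df.loc[valid, "p_value"], method="fdr_bh")[1]
        df["fdr"] = fdr
        df["large_delta"] = df["delta_psi"].abs() > delta_flag
    else:
        df["fdr"] = []
        df["large_delta"] = []
    return df
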