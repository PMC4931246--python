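"""Reproducible simulation experiments: detection sensitivity and Psi bias.

These functions wire the simulator to the detection and quantification code
under fixed study conditions; the acceptance script and the statistical
tests call them with fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bsj_support import BsjReadPair, call_bsj_minimal
from .config import RunConfig
from .formats_io import CircEntry, index_alignments
from .fsj_cirexon import FsjCandidate, detect_fsj_candidates
from .psi_quant import (
    InsertLengthDist,
    RouteCoordinates,
    collect_support_observations,
    estimate_psi,
    junction_context,
)
from .simulator import (
    InsertModel,
    SimParams,
    emit_reads,
    evaluate_against_truth,
    make_genome,
    sample_insert_length,
    simulate_circ_transcripts,
    simulate_library,
)

__all__ = ["sensitivity_run", "psi_bias_grid", "empirical_insert_dist"]


def sensitivity_run(
    insert_model: InsertModel,
    seed: int,
    n_circ: int = 160,
    depth: float = 25.0,
    read_length: int = 100,
    config: Optional[RunConfig] = None,
) -> Dict[str, object]:
    """End-to-end cirexon detection sensitivity on one simulated library.

    Simulates a mini-genome library (idealized split alignments), calls BSJs
    de novo with the minimal chiastic caller, runs the full cirexon
    detection, and scores boundaries against truth at +-2 bp.
    """
    from .pipeline import run_detect  # local import; pipeline imports nothing here

    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    params = SimParams(
        read_length=read_length,
        depth=depth,
        insert=insert_model,
        n_circ=n_circ,
        es_fraction=0.0,
        linear_fold=10.0,
        emit_sequences=False,
    )
    result = simulate_library(params, rng)
    alignments = index_alignments(result.segments)
    called = call_bsj_minimal(alignments, result.genome, cfg)
    detect = run_detect(result.genome, alignments, called, exon_index=None, config=cfg)
    cirexons_by_circ = {
        cid: [(cx.start, cx.end) for cx in res.cirexons]
        for cid, res in detect.circ_results.items()
    }
    metrics = evaluate_against_truth(called, cirexons_by_circ, result.circles, tol=2)
    return metrics


def empirical_insert_dist(
    insert_model: InsertModel,
    rng: np.random.Generator,
    read_length: int = 100,
    n_draws: int = 200_000,
    smooth_sigma: float = 5.0,
) -> InsertLengthDist:
    """Library insert-length model from a large sample of fragment draws.

    Mirrors what genome-wide estimation over millions of mRNA pairs yields in
    a real library: the distribution of emitted fragments (truncated below
    the read length, since such fragments are never sequenced as pairs).
    """
    lengths = [
        sample_insert_length(insert_model, rng, min_length=read_length)
        for _ in range(n_draws)
    ]
    return InsertLengthDist(lengths, min_pairs=1000, smooth_sigma=smooth_sigma)


def _truth_junctions(circle) -> Optional[Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]]:
    """Genomic (donor, acceptor) of the two inclusion junctions flanking the
    skipped exon and of the exclusion (skipping) junction."""
    k = circle.skipped_idx
    if k is None or k <= 0 or k >= len(circle.exons) - 1:
        return None
    prev_e = circle.exons[k - 1][1]
    s2, e2 = circle.exons[k]
    next_s = circle.exons[k + 1][0]
    return (prev_e, s2), (e2, next_s), (prev_e, next_s)


def psi_bias_grid(
    psis: Sequence[float] = (0.25, 0.5, 0.75),
    depths: Sequence[float] = (25.0, 50.0, 75.0, 100.0),
    n_circles: int = 50,
    insert_model: Optional[InsertModel] = None,
    seed: int = 0,
    read_length: int = 100,
    config: Optional[RunConfig] = None,
) -> List[Dict[str, float]]:
    """Raw vs corrected Psi over the (true Psi) x (depth) grid.

    Every cell simulates ``n_circles`` exon-skipping circRNAs at the assigned
    Psi, collects BSJ read pairs (truth-anchored: this experiment calibrates
    the estimator given the event, not event detectability), counts junction
    support via split-alignment FSJ detection, and estimates Psi with and
    without the insert-length correction.  Returns one row per cell with the
    mean estimates and biases.
    """
    cfg = config or RunConfig()
    model = insert_model or InsertModel(280.0, 80.0, 370.0, 100.0, 0.9)
    rng = np.random.default_rng(seed)
    genome, genes = make_genome(
        rng,
        n_genes=n_circles + 5,
        exons_per_gene=(3, 5),
        exon_len=(150, 260),
    )
    dist = empirical_insert_dist(model, rng, read_length)
    rows: List[Dict[str, float]] = []
    for psi in psis:
        for depth in depths:
            params = SimParams(
                read_length=read_length,
                depth=depth,
                insert=model,
                n_circ=n_circles,
                exons_per_circle=(3, 3),
                es_fraction=1.0,
                psi=psi,
                linear_fold=0.0,
                emit_sequences=False,
            )
            circles = simulate_circ_transcripts(genes, params, rng)
            result = emit_reads(circles, genes, genome, params, rng)
            alignments = index_alignments(result.segments)
            bsj_ids = result.bsj_pair_ids()
            raws, corrs = [], []
            for circle in circles:
                junctions = _truth_junctions(circle)
                if junctions is None:
                    continue
                rids = sorted(bsj_ids.get(circle.circ_id, ()))
                if not rids:
                    continue
                circ_entry = CircEntry(
                    circle.circ_id, circle.chrom, circle.start, circle.end,
                    circle.strand, set(rids),
                )
                pairs = [
                    BsjReadPair(circle.circ_id, rid, alignments[rid]) for rid in rids
                ]
                pairs_by_id = {rid: alignments[rid] for rid in rids}
                votes = detect_fsj_candidates(pairs, circ_entry, cfg)
                support: Dict[Tuple[int, int], Dict[str, Tuple[int, str]]] = {}
                for v in votes:
                    support.setdefault((v.donor, v.acceptor), {}).setdefault(
                        v.read_id, (v.mate, v.seg_strand)
                    )
                j1, j2, j_out = junctions
                fsjs = {}
                for key in (j1, j2, j_out):
                    if key in support:
                        fsjs[key] = FsjCandidate(
                            circle.chrom, key[0], key[1], "GT-AG", True, support[key]
                        )
                inc_iso, exc_iso = circle.isoforms[0], circle.isoforms[1]
                coords_in = RouteCoordinates(
                    [circle.exons[i] for i in inc_iso.exon_idx], circle.strand
                )
                coords_out = RouteCoordinates(
                    [circle.exons[i] for i in exc_iso.exon_idx], circle.strand
                )
                obs1 = (
                    collect_support_observations(fsjs[j1], pairs_by_id, coords_in)
                    if j1 in fsjs else []
                )
                obs2 = (
                    collect_support_observations(fsjs[j2], pairs_by_id, coords_in)
                    if j2 in fsjs else []
                )
                obs_out = (
                    collect_support_observations(fsjs[j_out], pairs_by_id, coords_out)
                    if j_out in fsjs else []
                )
                est = estimate_psi(
                    circle.circ_id, "ES", tuple(circle.exons[circle.skipped_idx]),
                    obs1, obs2, obs_out, dist,
                    coords_in.J, coords_out.J,
                    dominance_ratio=cfg.dominance_ratio,
                    ctx1=junction_context(coords_in, *j1, read_length),
                    ctx2=junction_context(coords_in, *j2, read_length),
                    ctx_out=junction_context(coords_out, *j_out, read_length),
                )
                if est is None or est.psi_raw is None:
                    continue
                if est.psi_corrected is None:
                    continue
                raws.append(est.psi_raw)
                corrs.append(est.psi_corrected)
            rows.append(
                {
                    "psi": float(psi),
                    "depth": float(depth),
                    "n_events": len(raws),
                    "mean_raw": float(np.mean(raws)) if raws else float("nan"),
                    "mean_corrected": float(np.mean(corrs)) if corrs else float("nan"),
                    "bias_raw": float(np.mean(raws) - psi) if raws else float("nan"),
                    "bias_corrected": (
                        float(np.mean(corrs) - psi) if corrs else float("nan")
                    ),
                }
            )
    return rows
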