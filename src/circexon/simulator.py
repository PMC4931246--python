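"""circRNA-containing paired-end RNA-seq simulator and evaluator.

Generates a synthetic mini-genome with multi-exon gene models, simulates
circRNAs (optionally with an exon-skipping isoform at an assigned Psi),
draws insert lengths from a two-component normal mixture via the Box-Muller
transform, places fragments uniformly on the circle (rolling circle: reads
wrap past the back-spliced junction), and emits FASTQ, an idealized SAM of
each read's true local alignments, and truth tables for evaluation.

Linear mRNA background reads are co-emitted so that depth testing, rescue
and insert-length estimation face realistic interference; a handful of long
single-exon genes provide the never-alternatively-spliced exons the
insert-length estimator needs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .formats_io import AlignmentSegment, CircEntry, Genome, make_circ_id
from .splice import revcomp

__all__ = [
    "InsertModel",
    "INSERT_PRESETS",
    "SimParams",
    "SimGene",
    "SimCircle",
    "SimResult",
    "sample_insert_length",
    "make_genome",
    "write_gtf",
    "write_genome_fasta",
    "simulate_circ_transcripts",
    "emit_reads",
    "simulate_library",
    "write_sam",
    "write_fastq",
    "write_truth",
    "evaluate_against_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class InsertModel:
    """Two-component normal mixture of insert lengths (weight p on comp. 1)."""

    mu1: float
    sigma1: float
    mu2: float = 0.0
    sigma2: float = 1.0
    p: float = 1.0

    def mean(self) -> float:
        return self.p * self.mu1 + (1.0 - self.p) * self.mu2

    def var(self) -> float:
        m = self.mean()
        return (
            self.p * (self.sigma1**2 + (self.mu1 - m) ** 2)
            + (1.0 - self.p) * (self.sigma2**2 + (self.mu2 - m) ** 2)
        )


#: The four library insert models used throughout the evaluation runs.
INSERT_PRESETS: Dict[str, InsertModel] = {
    "single280": InsertModel(280.0, 80.0),
    "mix280_370": InsertModel(280.0, 80.0, 370.0, 100.0, 0.9),
    "single400": InsertModel(400.0, 80.0),
    "mix550_280": InsertModel(550.0, 80.0, 280.0, 100.0, 0.85),
}


def sample_insert_length(
    model: InsertModel,
    rng: np.random.Generator,
    min_length: Optional[int] = None,
    max_tries: int = 1000,
) -> int:
    """Draw one insert length L via the Box-Muller transform.

    Three independent uniforms x1, x2, x3 are drawn; x1 selects the mixture
    component, and L = mu + sigma * sqrt(-2 ln x2) * cos(2 pi x3), rounded.
    With ``min_length`` set, draws below it are rejected and resampled (a
    fragment must not be shorter than a read).
    """
    for _ in range(max_tries):
        x1, x2, x3 = rng.random(3)
        if x1 <= model.p:
            mu, sigma = model.mu1, model.sigma1
        else:
            mu, sigma = model.mu2, model.sigma2
        x2 = max(x2, 1e-300)
        L = int(round(mu + sigma * math.sqrt(-2.0 * math.log(x2)) * math.cos(2.0 * math.pi * x3)))
        if min_length is None or L >= min_length:
            return L
    return max(int(round(model.mean())), min_length or 1)


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]  # 1-based inclusive, genomic order

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class SimIsoform:
    exon_idx: Tuple[int, ...]  # indices into the circle's exon list
    psi: float

    def circumference(self, exons: Sequence[Tuple[int, int]]) -> int:
        return sum(exons[i][1] - exons[i][0] + 1 for i in self.exon_idx)


@dataclass
class SimCircle:
    circ_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]  # genomic order
    isoforms: List[SimIsoform]
    skipped_idx: Optional[int] = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class SimParams:
    """Study conditions for one simulated library."""

    read_length: int = 100
    depth: float = 25.0
    insert: InsertModel = field(default_factory=lambda: INSERT_PRESETS["mix280_370"])
    n_circ: int = 160
    exons_per_circle: Tuple[int, int] = (2, 4)
    es_fraction: float = 0.0
    psi: float = 0.5
    linear_fold: float = 10.0
    min_segment: int = 10
    error_rate: float = 0.0
    emit_sequences: bool = True


@dataclass
class SimPairTruth:
    read_id: str
    circ_id: str
    iso_idx: int
    frag_start: int
    insert_length: int
    crosses_bsj: bool


@dataclass
class SimResult:
    genome: Genome
    genes: List[SimGene]
    circles: List[SimCircle]
    segments: List[AlignmentSegment]
    pair_truth: List[SimPairTruth]
    reads: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    def bsj_pair_ids(self) -> Dict[str, set]:
        out: Dict[str, set] = {}
        for pt in self.pair_truth:
            if pt.crosses_bsj:
                out.setdefault(pt.circ_id, set()).add(pt.read_id)
        return out

    def truth_circ_entries(self) -> List[CircEntry]:
        ids = self.bsj_pair_ids()
        out = []
        for c in self.circles:
            rids = ids.get(c.circ_id, set())
            if rids:
                out.append(
                    CircEntry(c.circ_id, c.chrom, c.start, c.end, c.strand, rids)
                )
        return out


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def make_genome(
    rng: np.random.Generator,
    n_genes: int = 160,
    n_long_genes: int = 12,
    exons_per_gene: Tuple[int, int] = (4, 7),
    exon_len: Tuple[int, int] = (120, 400),
    intron_len: Tuple[int, int] = (300, 800),
    intergenic: Tuple[int, int] = (500, 1500),
    long_exon_len: Tuple[int, int] = (1800, 2400),
    minus_fraction: float = 0.5,
    chrom: str = "chrS",
) -> Tuple[Genome, List[SimGene]]:
    """Random mini-genome with spliceable gene models.

    Every exon is flanked by canonical splice signals on its gene's strand
    (introns read GT..AG on '+', CT..AC on '-'; the same dinucleotides are
    planted just outside gene-terminal exons so back-splice signals exist for
    any run of exons).  Long single-exon genes provide constitutive exons for
    insert-length estimation.
    """
    chunks: List[str] = []
    pos = 0  # 0-based running length
    genes: List[SimGene] = []

    def emit(seq: str):
        nonlocal pos
        chunks.append(seq)
        pos += len(seq)

    for gi in range(n_genes + n_long_genes):
        long_gene = gi >= n_genes
        strand = "-" if rng.random() < minus_fraction else "+"
        # genomic-left flank of an exon carries the acceptor-side signal,
        # genomic-right flank the donor-side signal, in strand orientation
        left_sig = "AG" if strand == "+" else "AC"
        right_sig = "GT" if strand == "+" else "CT"
        emit(_random_bases(rng, int(rng.integers(intergenic[0], intergenic[1] + 1))))
        emit(left_sig)
        n_ex = 1 if long_gene else int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exons = []
        for ei in range(n_ex):
            if ei > 0:
                ilen = int(rng.integers(intron_len[0], intron_len[1] + 1))
                emit(right_sig + _random_bases(rng, max(ilen - 4, 1)) + left_sig)
            lo, hi = long_exon_len if long_gene else exon_len
            elen = int(rng.integers(lo, hi + 1))
            start = pos + 1  # 1-based
            emit(_random_bases(rng, elen))
            exons.append((start, pos))
        emit(right_sig)
        prefix = "lx" if long_gene else "g"
        genes.append(SimGene(f"{prefix}{gi}", chrom, strand, exons))
    emit(_random_bases(rng, 500))
    genome = Genome({chrom: "".join(chunks)})
    return genome, genes


def write_genome_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms():
            fh.write(f">{chrom}\n")
            seq = genome.fetch(chrom, 1, genome.length(chrom))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(genes: Sequence[SimGene], path: str, source: str = "sim") -> None:
    with open(path, "w") as fh:
        for g in genes:
            for s, e in g.exons:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "t_{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def simulate_circ_transcripts(
    genes: Sequence[SimGene],
    params: SimParams,
    rng: np.random.Generator,
) -> List[SimCircle]:
    """Pick runs of consecutive annotated exons as circRNAs.

    One circle per eligible multi-exon gene; a circle carrying an
    exon-skipping event needs at least three exons, and the skipped cirexon
    is drawn uniformly from its internal exons.  The two isoforms are
    recorded with the assigned Psi (inclusion) and 1 - Psi.
    """
    eligible = [g for g in genes if len(g.exons) >= 2 and not g.gene_id.startswith("lx")]
    if params.n_circ > len(eligible):
        warnings.warn(
            f"only {len(eligible)} multi-exon genes available for "
            f"{params.n_circ} requested circRNAs"
        )
    chosen = list(rng.permutation(len(eligible))[: params.n_circ])
    circles: List[SimCircle] = []
    for idx in chosen:
        g = eligible[int(idx)]
        with_es = rng.random() < params.es_fraction and len(g.exons) >= 3
        k_lo, k_hi = params.exons_per_circle
        if with_es:
            k_lo = max(k_lo, 3)
        k = int(rng.integers(k_lo, min(k_hi, len(g.exons)) + 1))
        first = int(rng.integers(0, len(g.exons) - k + 1))
        exons = list(g.exons[first : first + k])
        all_idx = tuple(range(k))
        if with_es:
            skipped = int(rng.integers(1, k - 1))
            isoforms = [
                SimIsoform(all_idx, params.psi),
                SimIsoform(tuple(i for i in all_idx if i != skipped), 1.0 - params.psi),
            ]
        else:
            skipped = None
            isoforms = [SimIsoform(all_idx, 1.0)]
        circles.append(
            SimCircle(
                make_circ_id(g.chrom, exons[0][0], exons[-1][1]),
                g.gene_id,
                g.chrom,
                g.strand,
                exons,
                isoforms,
                skipped,
            )
        )
    circles.sort(key=lambda c: (c.chrom, c.start, c.end))
    return circles


class _TranscriptMap:
    """Transcript-offset to genome mapping over an ordered exon chain."""

    def __init__(self, chrom: str, strand: str, exons: Sequence[Tuple[int, int]]):
        self.chrom = chrom
        self.strand = strand
        self.exons = list(exons)  # genomic order
        order = self.exons if strand == "+" else list(reversed(self.exons))
        self._order = order
        self._cum = [0]
        for s, e in order:
            self._cum.append(self._cum[-1] + e - s + 1)
        self.length = self._cum[-1]

    def blocks(self, ta: int, tb: int) -> List[Tuple[int, int, int, int]]:
        """Split transcript interval [ta, tb) at exon boundaries.

        Returns (piece_ta, piece_tb, g_lo, g_hi): the genomic block (1-based
        inclusive) covered by each transcript sub-interval.
        """
        out = []
        for (s, e), base in zip(self._order, self._cum):
            top = base + e - s + 1
            lo, hi = max(ta, base), min(tb, top)
            if lo >= hi:
                continue
            if self.strand == "+":
                g_lo = s + (lo - base)
                g_hi = s + (hi - base) - 1
            else:
                g_hi = e - (lo - base)
                g_lo = e - (hi - base) + 1
            out.append((lo, hi, g_lo, g_hi))
        out.sort(key=lambda b: b[0])
        return out

    def sequence(self, genome: Genome) -> str:
        seq = "".join(genome.fetch(self.chrom, s, e) for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


def _make_segment(
    rid: str, mate: int, chrom: str, strand: str, g_lo: int, qs: int, qe: int, rl: int
) -> AlignmentSegment:
    m = qe - qs
    lead, trail = (qs, rl - qe) if strand == "+" else (rl - qe, qs)
    cigar = []
    if lead:
        cigar.append(("S", lead))
    cigar.append(("M", m))
    if trail:
        cigar.append(("S", trail))
    return AlignmentSegment(
        read_id=rid, mate=mate, chrom=chrom, pos=g_lo, strand=strand,
        cigar=tuple(cigar), query_start=qs, query_end=qe, mapq=60, read_length=rl,
    )


def _fragment_segments(
    rid: str,
    tmap: _TranscriptMap,
    s: int,
    L: int,
    rl: int,
    circular: bool,
    min_segment: int,
) -> List[AlignmentSegment]:
    """True local alignments of both reads of one fragment.

    Mate 1 reads the transcript forward from s; mate 2 reads backward from
    s+L-1.  For circular templates the coordinates wrap modulo the
    circumference; blocks shorter than ``min_segment`` are unmappable and
    dropped.
    """
    J = tmap.length
    segs: List[AlignmentSegment] = []
    for mate, ta, tb in ((1, s, s + rl), (2, s + L - rl, s + L)):
        pieces: List[Tuple[int, int, int, int]] = []
        if circular:
            t = ta
            while t < tb:
                wrap_end = ((t // J) + 1) * J
                hi = min(tb, wrap_end)
                for pa, pb, g_lo, g_hi in tmap.blocks(t % J, t % J + (hi - t)):
                    pieces.append((t + (pa - t % J), t + (pb - t % J), g_lo, g_hi))
                t = hi
        else:
            pieces = tmap.blocks(ta, tb)
        fwd_strand = tmap.strand if mate == 1 else ("-" if tmap.strand == "+" else "+")
        for pa, pb, g_lo, g_hi in pieces:
            if pb - pa < min_segment:
                continue
            if mate == 1:
                qs, qe = pa - ta, pb - ta
            else:
                qs, qe = (ta + rl) - pb, (ta + rl) - pa
            segs.append(
                _make_segment(rid, mate, tmap.chrom, fwd_strand, g_lo, qs, qe, rl)
            )
    return segs


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = _BASES[rng.integers(0, 4)]
    return arr.tobytes().decode()


def emit_reads(
    circles: Sequence[SimCircle],
    genes: Sequence[SimGene],
    genome: Genome,
    params: SimParams,
    rng: np.random.Generator,
) -> SimResult:
    """Generate fragments for every circular isoform and the linear background.

    Pairs per isoform follow depth * J / (2 * read_length), scaled by the
    isoform's Psi; fragment starts are uniform on the circle and the insert
    length is resampled when shorter than a read.  Linear mRNA fragments are
    placed uniformly on each gene's spliced transcript at ``linear_fold``
    coverage.  Read ids encode provenance.
    """
    rl = params.read_length
    segments: List[AlignmentSegment] = []
    pair_truth: List[SimPairTruth] = []
    reads: Dict[str, Tuple[str, str]] = {}

    for ci, circ in enumerate(circles):
        for ii, iso in enumerate(circ.isoforms):
            exons = [circ.exons[i] for i in iso.exon_idx]
            tmap = _TranscriptMap(circ.chrom, circ.strand, exons)
            J = tmap.length
            if J < 50:
                warnings.warn(f"{circ.circ_id}: circle shorter than 50 bp skipped")
                continue
            seq = tmap.sequence(genome) if params.emit_sequences else ""
            n_pairs = int(round(iso.psi * params.depth * J / (2.0 * rl)))
            for k in range(n_pairs):
                s = int(rng.integers(0, J))
                L = sample_insert_length(params.insert, rng, min_length=rl)
                rid = f"sim:{ci}:{ii}:{k}"
                segments.extend(
                    _fragment_segments(rid, tmap, s, L, rl, True, params.min_segment)
                )
                crosses = (s + rl - 1 >= J) or (
                    (s + L - 1) // J > (s + L - rl) // J
                )
                pair_truth.append(SimPairTruth(rid, circ.circ_id, ii, s, L, crosses))
                if params.emit_sequences:
                    tile = seq * ((s + L) // J + 1)
                    r1 = _apply_errors(tile[s : s + rl], params.error_rate, rng)
                    r2 = _apply_errors(
                        revcomp(tile[s + L - rl : s + L]), params.error_rate, rng
                    )
                    reads[rid] = (r1, r2)

    if params.linear_fold > 0:
        for g in genes:
            tmap = _TranscriptMap(g.chrom, g.strand, g.exons)
            T = tmap.length
            if T < rl:
                continue
            seq = tmap.sequence(genome) if params.emit_sequences else ""
            n_pairs = int(round(params.linear_fold * T / (2.0 * rl)))
            for k in range(n_pairs):
                L = None
                for _ in range(50):
                    cand = sample_insert_length(params.insert, rng, min_length=rl)
                    if cand <= T:
                        L = cand
                        break
                if L is None:
                    continue
                s = int(rng.integers(0, T - L + 1))
                rid = f"lin:{g.gene_id}:{k}"
                segments.extend(
                    _fragment_segments(rid, tmap, s, L, rl, False, params.min_segment)
                )
                if params.emit_sequences:
                    r1 = _apply_errors(seq[s : s + rl], params.error_rate, rng)
                    r2 = _apply_errors(
                        revcomp(seq[s + L - rl : s + L]), params.error_rate, rng
                    )
                    reads[rid] = (r1, r2)

    return SimResult(genome, list(genes), list(circles), segments, pair_truth, reads)


def simulate_library(
    params: SimParams,
    rng: np.random.Generator,
    genome: Optional[Genome] = None,
    genes: Optional[List[SimGene]] = None,
    **genome_kwargs,
) -> SimResult:
    """Genome + circles + reads in one call (new mini-genome unless given)."""
    if genome is None or genes is None:
        genome, genes = make_genome(rng, n_genes=max(params.n_circ, 10), **genome_kwargs)
    circles = simulate_circ_transcripts(genes, params, rng)
    return emit_reads(circles, genes, genome, params, rng)


def write_sam(result: SimResult, path: str) -> None:
    """Idealized SAM: each read's true local alignments, soft-clipped."""
    genome = result.genome
    by_read: Dict[Tuple[str, int], List[AlignmentSegment]] = {}
    for seg in result.segments:
        by_read.setdefault((seg.read_id, seg.mate), []).append(seg)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in genome.chroms():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{genome.length(chrom)}\n")
        for (rid, mate) in sorted(by_read):
            segs = sorted(by_read[(rid, mate)], key=lambda s: (s.query_start, s.pos))
            primary = max(segs, key=lambda s: s.query_end - s.query_start)
            seq_pair = result.reads.get(rid)
            for seg in segs:
                flag = 0x1 | (0x40 if mate == 1 else 0x80)
                if seg.strand == "-":
                    flag |= 0x10
                seq = "*"
                if seg is not primary:
                    flag |= 0x800
                elif seq_pair is not None:
                    seq = seq_pair[mate - 1]
                    if seg.strand == "-":
                        seq = revcomp(seq)
                cigar = "".join(f"{n}{op}" for op, n in seg.cigar)
                fh.write(
                    f"{rid}\t{flag}\t{seg.chrom}\t{seg.pos}\t{seg.mapq}\t{cigar}"
                    f"\t*\t0\t0\t{seq}\t*\n"
                )


def write_fastq(result: SimResult, path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid in sorted(result.reads):
            r1, r2 = result.reads[rid]
            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def write_truth(result: SimResult, path: str) -> None:
    """Truth tables (JSON): circles, isoforms with Psi, per-circle BSJ pairs."""
    bsj = result.bsj_pair_ids()
    payload = {
        "circles": [
            {
                "circ_id": c.circ_id,
                "gene_id": c.gene_id,
                "chrom": c.chrom,
                "strand": c.strand,
                "exons": c.exons,
                "skipped_idx": c.skipped_idx,
                "isoforms": [
                    {"exon_idx": list(iso.exon_idx), "psi": iso.psi}
                    for iso in c.isoforms
                ],
                "n_bsj_pairs": len(bsj.get(c.circ_id, ())),
            }
            for c in result.circles
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_truth(path: str) -> List[SimCircle]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for c in payload["circles"]:
        out.append(
            SimCircle(
                c["circ_id"], c["gene_id"], c["chrom"], c["strand"],
                [tuple(e) for e in c["exons"]],
                [SimIsoform(tuple(i["exon_idx"]), i["psi"]) for i in c["isoforms"]],
                c.get("skipped_idx"),
            )
        )
    return out


def evaluate_against_truth(
    called: Sequence[CircEntry],
    cirexons_by_circ: Mapping[str, Sequence[Tuple[int, int]]],
    truth_circles: Sequence[SimCircle],
    tol: int = 2,
) -> Dict[str, object]:
    """Sensitivity/precision of BSJ calls and cirexon boundaries vs truth.

    A truth BSJ is detected when a called circRNA matches both back-splice
    coordinates within +-tol bp; a truth cirexon is detected when the
    matching called circRNA reports a cirexon with both boundaries within
    +-tol bp.  Overall cirexon sensitivity charges undetected circRNAs with
    all their cirexons; the conditional form restricts the denominator to
    detected circRNAs.
    """
    matched: Dict[str, Optional[str]] = {}
    used_called = set()
    for tc in truth_circles:
        hit = None
        for ce in called:
            if (
                ce.chrom == tc.chrom
                and abs(ce.start - tc.start) <= tol
                and abs(ce.end - tc.end) <= tol
            ):
                hit = ce.circ_id
                used_called.add(ce.circ_id)
                break
        matched[tc.circ_id] = hit

    n_truth = len(truth_circles)
    n_detected = sum(1 for v in matched.values() if v is not None)
    total_cirexons = 0
    cond_cirexons = 0
    found = 0
    for tc in truth_circles:
        truth_ex = sorted(tc.exons)
        total_cirexons += len(truth_ex)
        hit = matched[tc.circ_id]
        if hit is None:
            continue
        cond_cirexons += len(truth_ex)
        predicted = list(cirexons_by_circ.get(hit, ()))
        for s, e in truth_ex:
            if any(abs(ps - s) <= tol and abs(pe - e) <= tol for ps, pe in predicted):
                found += 1

    return {
        "n_truth_circ": n_truth,
        "n_called_circ": len(called),
        "bsj_sensitivity": n_detected / n_truth if n_truth else 0.0,
        "bsj_precision": len(used_called) / len(called) if called else 0.0,
        "n_truth_cirexons": total_cirexons,
        "n_truth_cirexons_detected_circ": cond_cirexons,
        "n_cirexons_found": found,
        "cirexon_sensitivity": found / total_cirexons if total_cirexons else 0.0,
        "cirexon_sensitivity_conditional": (
            found / cond_cirexons if cond_cirexons else 0.0
        ),
    }
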