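"""Readers and writers for external formats.

SAM alignments are read through pysam, the genome through pyfaidx, GTF exon
models into an intervaltree-backed index, and the circRNA list plus all
output tables through pandas.  All coordinates are 1-based inclusive except
where a format dictates otherwise (BED export only).
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
import pysam
from intervaltree import IntervalTree

__all__ = [
    "FormatError",
    "AlignmentSegment",
    "ExonModel",
    "CircEntry",
    "Genome",
    "ExonIndex",
    "read_sam",
    "index_alignments",
    "read_gtf",
    "read_circ_list",
    "write_circ_list",
    "write_outputs",
    "read_cirexon_table",
    "read_as_table",
    "parse_circ_id",
    "make_circ_id",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# CIGAR operations that consume query / reference, per the SAM spec.
_CONSUMES_QUERY = set("MIS=X")
_CONSUMES_REF = set("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class AlignmentSegment:
    """One local alignment of (part of) a read.

    ``query_start``/``query_end`` are 0-based half-open offsets of the aligned
    portion within the read in its *original* (sequenced) orientation, so that
    sorting segments of one read by ``query_start`` reproduces the order in
    which the read traverses its template.
    """

    read_id: str
    mate: int
    chrom: str
    pos: int  # 1-based leftmost reference coordinate
    strand: str  # '+' or '-'
    cigar: Tuple[Tuple[str, int], ...]
    query_start: int
    query_end: int
    mapq: int
    read_length: int

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end:
            raise ValueError("query_start must be < query_end")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _CONSUMES_REF)

    @property
    def ref_end(self) -> int:
        """1-based inclusive rightmost reference coordinate."""
        return self.pos + self.ref_span - 1

    def ref_blocks(self) -> List[Tuple[int, int]]:
        """Aligned (M/=/X) reference blocks as 1-based inclusive intervals."""
        blocks = []
        p = self.pos
        for op, n in self.cigar:
            if op in "M=X":
                blocks.append((p, p + n - 1))
            if op in _CONSUMES_REF:
                p += n
        return blocks


def parse_cigar(text: str) -> Tuple[Tuple[str, int], ...]:
    if text == "*" or not text:
        raise FormatError("missing CIGAR")
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text)]
    if "".join(f"{n}{op}" for op, n in ops) != text:
        raise FormatError(f"malformed CIGAR {text!r}")
    return tuple(ops)


def _segment_from_pysam(rec: "pysam.AlignedSegment") -> AlignmentSegment:
    cigar = tuple(
        ("MIDNSHP=XB"[op], n) for op, n in (rec.cigartuples or ())
    )
    if not cigar:
        raise FormatError("missing CIGAR")
    total = sum(n for op, n in cigar if op in _CONSUMES_QUERY or op == "H")
    lead = 0
    for op, n in cigar:
        if op in "SH":
            lead += n
        else:
            break
    trail = 0
    for op, n in reversed(cigar):
        if op in "SH":
            trail += n
        else:
            break
    qs, qe = lead, total - trail
    if rec.is_reverse:
        qs, qe = total - qe, total - qs
    mate = 2 if rec.is_paired and rec.is_read2 else 1
    return AlignmentSegment(
        read_id=rec.query_name,
        mate=mate,
        chrom=rec.reference_name,
        pos=rec.reference_start + 1,
        strand="-" if rec.is_reverse else "+",
        cigar=cigar,
        query_start=qs,
        query_end=qe,
        mapq=rec.mapping_quality,
        read_length=total,
    )


def read_sam(path: str, region: Optional[str] = None) -> Iterator[AlignmentSegment]:
    """Stream alignment segments from a SAM (or indexed BAM) file.

    Secondary and supplementary records are retained (split alignments are
    the core signal); duplicate-flagged and unmapped records are dropped.
    A malformed record raises :class:`FormatError` naming the record number.
    """
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        it = iter(fh.fetch(region=region) if region else fh)
        i = 0
        while True:
            i += 1
            try:
                rec = next(it)
            except StopIteration:
                return
            except (ValueError, OSError) as exc:
                raise FormatError(f"record {i} of {path}: {exc}") from exc
            if rec.is_unmapped or rec.is_duplicate:
                continue
            try:
                yield _segment_from_pysam(rec)
            except (FormatError, ValueError) as exc:
                raise FormatError(f"record {i} of {path}: {exc}") from exc


def index_alignments(
    segments: Iterable[AlignmentSegment],
) -> Dict[str, List[AlignmentSegment]]:
    """Group segments by read id (both mates together)."""
    out: Dict[str, List[AlignmentSegment]] = {}
    for seg in segments:
        out.setdefault(seg.read_id, []).append(seg)
    for segs in out.values():
        segs.sort(key=lambda s: (s.mate, s.query_start, s.chrom, s.pos))
    return out


@dataclass(frozen=True)
class ExonModel:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    gene_id: str
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("exon start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class ExonIndex:
    """Interval-searchable exon collection with per-gene transcript maps."""

    def __init__(self, exons: Iterable[ExonModel]):
        self._trees: Dict[str, IntervalTree] = {}
        self.genes: Dict[str, Dict[str, List[ExonModel]]] = {}
        n = 0
        for ex in exons:
            self._trees.setdefault(ex.chrom, IntervalTree()).addi(
                ex.start, ex.end + 1, ex
            )
            self.genes.setdefault(ex.gene_id, {}).setdefault(
                ex.transcript_id, []
            ).append(ex)
            n += 1
        for tx_map in self.genes.values():
            for exs in tx_map.values():
                exs.sort(key=lambda e: e.start)
        self.n_exons = n

    def query(self, chrom: str, start: int, end: int) -> List[ExonModel]:
        """All exons overlapping the 1-based inclusive interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        hits.sort(key=lambda e: (e.start, e.end, e.transcript_id))
        return hits

    def gene_transcripts(self, gene_id: str) -> Dict[str, List[ExonModel]]:
        return self.genes.get(gene_id, {})

    def gene_strand(self, gene_id: str) -> Optional[str]:
        for exs in self.genes.get(gene_id, {}).values():
            if exs:
                return exs[0].strand
        return None


def read_gtf(path: str) -> ExonIndex:
    """Load ``exon`` features of a GTF into an :class:`ExonIndex`.

    Lines without a transcript_id attribute are skipped; the skip count is
    reported via a single warning.
    """
    exons: List[ExonModel] = []
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{ln}: expected 9 GTF columns")
            if parts[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            if "transcript_id" not in attrs:
                skipped += 1
                continue
            exons.append(
                ExonModel(
                    chrom=parts[0],
                    start=int(parts[3]),
                    end=int(parts[4]),
                    strand=parts[6],
                    gene_id=attrs.get("gene_id", attrs["transcript_id"]),
                    transcript_id=attrs["transcript_id"],
                )
            )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} exon line(s) without transcript_id")
    return ExonIndex(exons)


_CIRC_ID_RE = re.compile(r"^(.+):([\d,]+)\|([\d,]+)$")


def parse_circ_id(circ_id: str) -> Tuple[str, int, int]:
    """Parse ``chrom:start|end``; thousands separators are accepted."""
    m = _CIRC_ID_RE.match(circ_id.strip())
    if not m:
        raise FormatError(f"unparsable circRNA id {circ_id!r}")
    return m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", ""))


def make_circ_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}|{end}"


@dataclass
class CircEntry:
    """One circRNA locus keyed by its back-spliced junction coordinates."""

    circ_id: str
    chrom: str
    start: int  # back-splice acceptor (smaller coordinate)
    end: int  # back-splice donor (larger coordinate)
    strand: str  # '+', '-' or '.'
    bsj_read_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("circRNA start must be < end")

    @property
    def bsj_count(self) -> int:
        return len(self.bsj_read_ids)


def read_circ_list(path: str) -> List[CircEntry]:
    """Read the circRNA list TSV.

    Columns: circ_id, chrom, start, end, strand, bsj_count, bsj_read_ids
    (comma-joined).  Rows with start >= end are rejected (and reported via a
    warning); a bsj_count disagreeing with the id list is recomputed;
    duplicate circ_ids are merged with unioned read ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        return []
    required = {"circ_id", "chrom", "start", "end", "strand", "bsj_count", "bsj_read_ids"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    merged: Dict[str, CircEntry] = {}
    rejected = 0
    for row in df.itertuples(index=False):
        chrom, start, end = parse_circ_id(row.circ_id)
        start2, end2 = int(str(row.start).replace(",", "")), int(str(row.end).replace(",", ""))
        if (chrom, start, end) != (row.chrom, start2, end2):
            raise FormatError(f"{path}: circ_id {row.circ_id!r} disagrees with coordinate columns")
        if start >= end:
            rejected += 1
            continue
        reads = {
            r for r in str(row.bsj_read_ids).split(",") if r and r != "nan"
        }
        if int(row.bsj_count) != len(reads):
            warnings.warn(
                f"{path}: bsj_count for {row.circ_id} recomputed from read id list"
            )
        cid = make_circ_id(chrom, start, end)
        if cid in merged:
            merged[cid].bsj_read_ids |= reads
        else:
            merged[cid] = CircEntry(cid, chrom, start, end, str(row.strand), reads)
    if rejected:
        warnings.warn(f"{path}: rejected {rejected} row(s) with start >= end")
    return sorted(merged.values(), key=lambda c: (c.chrom, c.start, c.end))


def write_circ_list(entries: Sequence[CircEntry], path: str) -> None:
    rows = [
        {
            "circ_id": c.circ_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "bsj_count": c.bsj_count,
            "bsj_read_ids": ",".join(sorted(c.bsj_read_ids)),
        }
        for c in sorted(entries, key=lambda c: (c.chrom, c.start, c.end))
    ]
    pd.DataFrame(
        rows,
        columns=["circ_id", "chrom", "start", "end", "strand", "bsj_count", "bsj_read_ids"],
    ).to_csv(path, sep="\t", index=False)


class Genome:
    """Random-access genome: pyfaidx-backed or an in-memory dict of strings."""

    def __init__(self, source):
        self._dict: Optional[Mapping[str, str]] = None
        self._fasta = None
        if isinstance(source, Mapping):
            self._dict = {k: str(v).upper() for k, v in source.items()}
        else:
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source))

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        return cls(path)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive substring; out-of-range is clipped."""
        if start > end:
            return ""
        if self._dict is not None:
            seq = self._dict.get(chrom, "")
            return seq[max(start - 1, 0) : end]
        return str(self._fasta[chrom][max(start - 1, 0) : end]).upper()

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict.get(chrom, ""))
        return len(self._fasta[chrom])

    def chroms(self) -> List[str]:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fasta.keys())


_CIREXON_COLS = ["circ_id", "chrom", "start", "end", "class", "evidence", "support5", "support3"]
_AS_COLS = [
    "circ_id",
    "event_type",
    "labels",
    "members",
    "c1",
    "c2",
    "c_out",
    "psi_raw",
    "psi_corrected",
    "correction_applied",
    "nested",
]


def write_outputs(cirexons, as_events, psi_table: Optional[pd.DataFrame], out_dir: str, header: str = "") -> Dict[str, str]:
    """Write the cirexon table, AS table and BED12 route track.

    ``cirexons`` is a sequence of (circ_id, Cirexon-like) pairs and
    ``as_events`` a sequence of dicts with the AS-table columns.  Returns the
    written paths.  Ordering is deterministic; with no events the files carry
    headers only.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    rows = []
    for circ_id, cx in cirexons:
        rows.append(
            {
                "circ_id": circ_id,
                "chrom": cx.chrom,
                "start": cx.start,
                "end": cx.end,
                "class": cx.annotation_class,
                "evidence": cx.evidence,
                "support5": cx.support5,
                "support3": cx.support3,
            }
        )
    cx_df = pd.DataFrame(rows, columns=_CIREXON_COLS)
    if len(cx_df):
        cx_df = cx_df.sort_values(["circ_id", "start", "end"], kind="mergesort")
    paths["cirexons"] = os.path.join(out_dir, "cirexons.tsv")
    _write_tsv(cx_df, paths["cirexons"], header)

    ev_df = pd.DataFrame(list(as_events), columns=_AS_COLS)
    if len(ev_df):
        ev_df = ev_df.sort_values(["circ_id", "event_type", "members"], kind="mergesort")
    paths["as_events"] = os.path.join(out_dir, "as_events.tsv")
    _write_tsv(ev_df, paths["as_events"], header)

    if psi_table is not None:
        paths["psi"] = os.path.join(out_dir, "psi.tsv")
        _write_tsv(psi_table, paths["psi"], header)

    paths["routes_bed"] = os.path.join(out_dir, "routes.bed")
    _write_routes_bed(cirexons, paths["routes_bed"])
    return paths


def _write_tsv(df: pd.DataFrame, path: str, header: str) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_routes_bed(cirexons, path: str) -> None:
    """BED12 track: one line per circRNA spanning its cirexons as blocks."""
    by_circ: Dict[str, List] = {}
    for circ_id, cx in cirexons:
        by_circ.setdefault(circ_id, []).append(cx)
    with open(path, "w") as fh:
        for circ_id in sorted(by_circ):
            cxs = sorted(by_circ[circ_id], key=lambda c: (c.start, c.end))
            merged = []
            for c in cxs:  # overlapping alternatives collapse to one block
                if merged and c.start <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], c.end)
                else:
                    merged.append([c.start, c.end])
            chrom = cxs[0].chrom
            start0 = merged[0][0] - 1  # BED is 0-based half-open
            end0 = merged[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in merged)
            starts = ",".join(str(s - 1 - start0) for s, e in merged)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [chrom, start0, end0, circ_id, 0, ".", start0, end0,
                         "0,0,0", len(merged), sizes, starts],
                    )
                )
                + "\n"
            )


def read_cirexon_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_as_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
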