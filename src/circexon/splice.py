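"""Canonical splice-signal lookup shared by the FSJ refiner and BSJ caller.

Junctions are stored genomically: ``donor`` is the last base of the left
exon and ``acceptor`` the first base of the right exon, whatever the
transcribed strand.  On the plus strand the intron then reads GT..AG; on the
minus strand the genome shows the reverse complement, CT..AC.
"""

from __future__ import annotations

from typing import Iterator, Optional, Tuple

from .formats_io import Genome

ORIENTATIONS = ("+", "-")


def fsj_signal_ok(genome: Genome, chrom: str, donor: int, acceptor: int, orientation: str) -> bool:
    """True when the intron (donor, acceptor) carries the canonical signal."""
    left = genome.fetch(chrom, donor + 1, donor + 2)
    right = genome.fetch(chrom, acceptor - 2, acceptor - 1)
    if orientation == "+":
        return left == "GT" and right == "AG"
    return left == "CT" and right == "AC"


def bsj_signal_ok(genome: Genome, chrom: str, start: int, end: int, orientation: str) -> bool:
    """True when a back-splice from ``end`` (donor) to ``start`` (acceptor)
    carries the canonical signal just outside the circle."""
    left = genome.fetch(chrom, start - 2, start - 1)
    right = genome.fetch(chrom, end + 1, end + 2)
    if orientation == "+":
        return left == "AG" and right == "GT"
    return left == "AC" and right == "CT"


def shift_pairs(window: int) -> Iterator[Tuple[int, int]]:
    """Joint boundary shifts ordered by total magnitude, then leftmost."""
    shifts = sorted(range(-window, window + 1), key=lambda s: (abs(s), s))
    for total in range(0, 2 * window + 1):
        for a in shifts:
            for b in shifts:
                if abs(a) + abs(b) == total:
                    yield a, b


def refine_junction(
    genome: Genome,
    chrom: str,
    left: int,
    right: int,
    window: int,
    kind: str = "fsj",
    strand_hint: Optional[str] = None,
) -> Optional[Tuple[int, int, str]]:
    """Search +-window around an estimated junction for a canonical signal.

    Returns (left, right, orientation) of the best placement: the one with
    minimal total shift from the alignment-implied breakpoints, ties broken
    leftmost, '+' before '-'.  ``kind`` selects forward- vs back-splice
    signal geometry.  None when no placement matches.
    """
    check = fsj_signal_ok if kind == "fsj" else bsj_signal_ok
    orientations = (strand_hint,) if strand_hint in ORIENTATIONS else ORIENTATIONS
    for da, db in shift_pairs(window):
        l, r = left + da, right + db
        if l >= r:
            continue
        for orientation in orientations:
            if check(genome, chrom, l, r, orientation):
                return l, r, orientation
    return None


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]
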