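"""Run configuration: every tunable threshold of the pipeline in one place.

All coordinates handled by the pipeline are 1-based inclusive (SAM/GTF
convention); BED export converts at the writer boundary only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    """Thresholds and windows for detection, refinement and quantification.

    Attributes
    ----------
    min_mapq:
        Minimum mapping quality for a segment to be counted anywhere.
    min_bsj_support:
        Distinct read pairs required for the minimal BSJ caller to emit a
        circRNA.
    bsj_signal_window:
        +-bp searched around the naive chiastic breakpoint for a GT/AG
        (or CT/AC) back-splice signal.
    max_query_gap:
        Maximum unaligned (or overlapping) read bases tolerated between two
        neighbouring segments voting for a junction.
    max_intron:
        Maximum reference gap of a forward splice junction.
    signal_window:
        +-bp searched around an estimated FSJ boundary for splice signals.
    min_unrefined_support:
        Read-pair support required to keep an FSJ cluster for which no
        canonical splice signal was found.
    min_rescue_support:
        Read-pair support required for a signal-refined FSJ recovered from
        non-BSJ reads during rescue.
    max_cirexon_candidate:
        Candidate cirexons longer than this are not accepted on junction
        pairing alone but deferred to depth testing.
    flank:
        Half-window (bases) on each side of a boundary for the depth
        discontinuity test.
    alpha:
        Significance level of the depth discontinuity test.
    dominance_ratio:
        c_max/c_min ratio above which only the dominant strand is used in the
        insert-length correction.
    long_exon_min:
        Minimum length of a constitutive exon used for insert-length
        estimation.
    min_insert_pairs:
        Minimum usable read pairs for the insert-length distribution; below
        this, Psi correction is disabled.
    insert_smooth_sigma:
        Gaussian kernel (bp) used to smooth the empirical insert-length
        histogram; 0 disables smoothing.
    min_bsj_cutoff:
        BSJ read-count cutoff applied when summarising per-type AS event
        frequencies across circRNAs.
    max_routes:
        Cap on enumerated routes per circRNA (truncation is flagged).
    boundary_tol:
        +-bp tolerance when matching cirexon boundaries to annotation.
    """

    min_mapq: int = 10
    min_bsj_support: int = 2
    bsj_signal_window: int = 5
    max_query_gap: int = 5
    max_intron: int = 200_000
    signal_window: int = 10
    min_unrefined_support: int = 3
    min_rescue_support: int = 1
    max_cirexon_candidate: int = 10_000
    flank: int = 50
    alpha: float = 0.05
    dominance_ratio: float = 10.0
    long_exon_min: int = 1000
    min_insert_pairs: int = 1000
    insert_smooth_sigma: float = 5.0
    min_bsj_cutoff: int = 20
    max_routes: int = 1000
    boundary_tol: int = 2
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))
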