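"""Relative-abundance (Psi) estimation with insert-length correction, and a
beta-binomial test for circRNA-vs-mRNA inclusion differences.

BSJ read pairs are anchored at the back-spliced junction, so the chance that
a pair also documents a given FSJ depends on where the required insert
length falls in the library's insert-length distribution -- and, through the
rolling circle, on the isoform circumference J: a fragment spanning from the
anchor to the junction may wrap the circle any number of times i, each wrap
adding J to the insert.  Supporting counts are therefore normalized by
sum_i P(K + J*i), the total probability of the insert lengths compatible
with the observed within-circle span K.  This removes the systematic
underestimation of Psi that raw BSJ-read ratios show (the inclusion isoform
always has the larger circumference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats
from scipy.ndimage import gaussian_filter1d

from .config import RunConfig
from .formats_io import AlignmentSegment, ExonIndex
from .fsj_cirexon import FsjCandidate

__all__ = [
    "InsertLengthDist",
    "PsiEstimate",
    "RouteCoordinates",
    "estimate_insert_distribution",
    "correct_support_count",
    "normalize_observations",
    "JunctionContext",
    "strand_mean_wrap_prob",
    "junction_context",
    "pair_insert_span",
    "collect_support_observations",
    "estimate_psi",
    "linear_psi_from_mrna",
    "betabinomial_diff_test",
]


class InsertLengthDist:
    """Empirical insert-length probability model P(K).

    Built from the outer spans of read pairs mapping fully inside long,
    never-alternatively-spliced exons.  The histogram may be smoothed with a
    small Gaussian kernel so that the wrap sums sum_i P(K + J*i) are not
    dominated by single-bin sampling noise.
    """

    def __init__(self, lengths: Sequence[int], min_pairs: int = 1000, smooth_sigma: float = 5.0):
        lengths = np.asarray([l for l in lengths if l > 0], dtype=np.int64)
        self.n = int(len(lengths))
        self.usable = self.n >= min_pairs
        if self.n == 0:
            self.pmf = np.zeros(1)
            return
        counts = np.bincount(lengths)
        if smooth_sigma and smooth_sigma > 0:
            sm = gaussian_filter1d(counts.astype(float), smooth_sigma, mode="constant")
        else:
            sm = counts.astype(float)
        self.pmf = sm / sm.sum()
        self._wrap_cache: Dict[int, "np.ndarray"] = {}

    @property
    def max_length(self) -> int:
        return len(self.pmf) - 1

    def prob(self, K: int) -> float:
        """P(K); zero outside the observed support."""
        if K < 0 or K > self.max_length:
            return 0.0
        return float(self.pmf[K])

    def wrap_prob_sum(self, K: int, J: int) -> float:
        """sum over i >= 0 of P(K + J*i), truncated at the histogram support."""
        if J <= 0:
            raise ValueError("circumference J must be positive")
        if K < 0:
            return 0.0
        if K > self.max_length:
            return 0.0
        return float(self.pmf[K::J].sum())

    def wrap_prob_vector(self, J: int) -> "np.ndarray":
        """sum_i P(r + J*i) for every residue r in [0, J) (cached per J)."""
        cached = self._wrap_cache.get(J)
        if cached is None:
            n = len(self.pmf)
            pad = (-n) % J
            arr = np.concatenate([self.pmf, np.zeros(pad)])
            cached = arr.reshape(-1, J).sum(axis=0)
            self._wrap_cache[J] = cached
        return cached

    def mean(self) -> float:
        return float(np.arange(len(self.pmf)) @ self.pmf)

    def floor(self) -> float:
        """Smallest positive probability mass (fallback for observed spans
        the finite histogram assigns zero to)."""
        pos = self.pmf[self.pmf > 0]
        return float(pos.min()) if len(pos) else 0.0


def _constitutive_long_exons(exon_index: ExonIndex, long_exon_min: int):
    """Exons >= long_exon_min present with identical boundaries in every
    transcript of their gene."""
    out = []
    for gene_id, tx_map in exon_index.genes.items():
        n_tx = len(tx_map)
        seen: Dict[Tuple[str, int, int], int] = {}
        for exs in tx_map.values():
            for ex in exs:
                key = (ex.chrom, ex.start, ex.end)
                seen[key] = seen.get(key, 0) + 1
        for (chrom, start, end), count in seen.items():
            if count == n_tx and end - start + 1 >= long_exon_min:
                out.append((chrom, start, end))
    return out


def estimate_insert_distribution(
    alignments: Mapping[str, List[AlignmentSegment]],
    exon_index: Optional[ExonIndex],
    config: Optional[RunConfig] = None,
) -> Optional[InsertLengthDist]:
    """Estimate P(K) from pairs inside long constitutive exons.

    Returns None when no annotation is available; an unusable distribution
    (too few pairs) is returned with ``usable=False`` and triggers a warning.
    """
    cfg = config or RunConfig()
    if exon_index is None:
        return None
    exons = _constitutive_long_exons(exon_index, cfg.long_exon_min)
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in exons:
        by_chrom.setdefault(chrom, []).append((s, e))
    spans: List[int] = []
    for rid in alignments:
        segs = alignments[rid]
        if len(segs) != 2:
            continue
        a, b = segs
        if (
            a.mate == b.mate
            or a.chrom != b.chrom
            or a.strand == b.strand
            or a.mapq < cfg.min_mapq
            or b.mapq < cfg.min_mapq
        ):
            continue
        lo = min(a.pos, b.pos)
        hi = max(a.ref_end, b.ref_end)
        if any(s <= lo and hi <= e for s, e in by_chrom.get(a.chrom, ())):
            spans.append(hi - lo + 1)
    dist = InsertLengthDist(spans, cfg.min_insert_pairs, cfg.insert_smooth_sigma)
    if not dist.usable:
        warnings.warn(
            f"only {dist.n} read pairs usable for the insert-length "
            "distribution; Psi correction disabled"
        )
    return dist


@dataclass
class JunctionContext:
    """Geometry needed to normalize a junction's support count.

    ``boundary_offset`` is the junction's transcript offset b on its isoform
    (the first base of the transcript-downstream exon); with the read length
    and the minimal mappable overhang it determines which within-circle
    spans K a supporting pair can exhibit on each strand.
    """

    coords: "RouteCoordinates"
    boundary_offset: int
    read_length: int
    overhang: int = 10


def strand_mean_wrap_prob(
    dist: InsertLengthDist,
    J: int,
    boundary: int,
    read_length: int,
    overhang: int,
    label: str,
) -> float:
    """Mean of sum_i P(K + J*i) over the spans K compatible with one strand.

    A supporting pair couples a BSJ-crossing read with a junction-covering
    read.  'fwd': the transcript-forward read covers the junction (its start
    s ranges over the covering window) and the reverse read crosses the BSJ
    (fragment end e ranges over the anchor residues); 'rev' is the mirror
    configuration.  Every (s, e) combination contributes its span
    K = (e - s) mod J + 1; the unweighted mean of the wrap-probability sums
    over this set is the exact per-count divisor.
    """
    rl, h, b = read_length, overhang, boundary
    if label == "fwd":
        s_lo, s_hi = b - rl + h, b - h
        e_lo, e_hi = 0, rl - 2
    else:
        s_lo, s_hi = J - rl + 1, J - 1
        e_lo, e_hi = b + h - 1, b + rl - h - 1
    n_s, n_e = s_hi - s_lo + 1, e_hi - e_lo + 1
    if n_s <= 0 or n_e <= 0:
        return 0.0
    # multiplicity of each offset d = e - s is the convolution of the two
    # uniform windows; K = d mod J + 1 indexes the cached wrap sums
    mult = np.convolve(np.ones(n_e), np.ones(n_s))
    d = np.arange(e_lo - s_hi, e_hi - s_lo + 1)
    qvec = dist.wrap_prob_vector(J)
    return float((mult * qvec[(d + 1) % J]).sum() / mult.sum())


def normalize_observations(
    observations: Sequence[Tuple[str, Optional[int]]],
    J: int,
    dist: InsertLengthDist,
    dominance_ratio: float = 10.0,
    context: Optional[JunctionContext] = None,
) -> Optional[float]:
    """Insert-length-corrected support from per-pair (strand, K) observations.

    With junction geometry available (``context``), each strand's count c is
    divided by the mean of sum_i P(K + J*i) over the spans compatible with
    that strand -- the count-level normalization, whose variance is limited
    by the count itself -- and the c_max >> c_min branch is decided on the
    *expected* strand shares (the ratio of those mean probabilities): when
    one strand is geometrically starved its tiny divisor would turn a single
    stray pair into a huge normalized count, so only the dominant strand is
    used, doubled (each strand's normalized count estimates the same
    quantity, making both branches estimate the same per-event value).
    Without geometry, each pair contributes 1 / sum_i P(K_pair + J*i) (the
    Horvitz-Thompson form of the same rule) and dominance falls back to the
    observed counts (c_max >= ratio * c_min, or c_min = 0).  Returns None
    when no usable probability sum exists.
    """
    strands: Dict[str, List[int]] = {"fwd": [], "rev": []}
    counts: Dict[str, int] = {"fwd": 0, "rev": 0}
    for label, K in observations:
        counts[label] = counts.get(label, 0) + 1
        if K is not None:
            strands.setdefault(label, []).append(K)
    c_fwd, c_rev = counts["fwd"], counts["rev"]
    if c_fwd + c_rev == 0:
        return None
    floor = dist.floor()

    if context is not None:
        q = {
            label: strand_mean_wrap_prob(
                dist, J, context.boundary_offset,
                context.read_length, context.overhang, label,
            )
            for label in ("fwd", "rev")
        }
        q_min, q_max = min(q.values()), max(q.values())
        if q_max <= 0:
            return None
        if q_min <= 0 or q_max >= dominance_ratio * q_min:
            label = "fwd" if q["fwd"] >= q["rev"] else "rev"
            return 2.0 * counts[label] / q[label]
        return counts["fwd"] / q["fwd"] + counts["rev"] / q["rev"]

    def one_strand(label: str) -> Optional[float]:
        total = 0.0
        for K in strands[label]:
            qk = dist.wrap_prob_sum(K, J)
            if qk <= 0:
                qk = floor
            if qk <= 0:
                return None
            total += 1.0 / qk
        return total

    c_min, c_max = min(c_fwd, c_rev), max(c_fwd, c_rev)
    if c_min == 0 or c_max >= dominance_ratio * c_min:
        label = "fwd" if c_fwd >= c_rev else "rev"
        val = one_strand(label)
        return None if val is None else 2.0 * val
    f, r = one_strand("fwd"), one_strand("rev")
    if f is None or r is None:
        return None
    return f + r


def correct_support_count(
    c_fwd: int,
    c_rev: int,
    K_fwd: Optional[int],
    K_rev: Optional[int],
    J: int,
    dist: InsertLengthDist,
    dominance_ratio: float = 10.0,
) -> Optional[float]:
    """Normalized support count c' for one junction.

    Scalar-K-per-strand convenience form of :func:`normalize_observations`:
    each strand's count c is divided by sum_i P(K + J*i) for its
    representative within-circle span K.  Returns None when the probability
    sums vanish (correction skipped for the event).
    """
    obs: List[Tuple[str, Optional[int]]] = []
    obs.extend(("fwd", K_fwd) for _ in range(c_fwd))
    obs.extend(("rev", K_rev) for _ in range(c_rev))
    return normalize_observations(obs, J, dist, dominance_ratio)


class RouteCoordinates:
    """Genome <-> transcript-offset mapping for one circular isoform.

    Offsets run 0..J-1 from the back-splice acceptor in transcript
    orientation (genomic left-to-right for '+', right-to-left for '-';
    unknown strand is treated as '+').
    """

    def __init__(self, exons: Sequence[Tuple[int, int]], strand: str, chrom: str = ""):
        self.exons = sorted((int(s), int(e)) for s, e in exons)
        self.strand = "+" if strand not in ("+", "-") else strand
        self.chrom = chrom
        lengths = [e - s + 1 for s, e in self.exons]
        self.J = sum(lengths)
        order = self.exons if self.strand == "+" else list(reversed(self.exons))
        self._order = order
        self._cum = np.concatenate([[0], np.cumsum([e - s + 1 for s, e in order])])

    def offset(self, pos: int) -> Optional[int]:
        """Transcript offset of a genomic position; None when intronic."""
        for (s, e), base in zip(self._order, self._cum):
            if s <= pos <= e:
                return int(base + (pos - s if self.strand == "+" else e - pos))
        return None

    def read_anchor_offset(self, segments: Sequence[AlignmentSegment]) -> Optional[int]:
        """Transcript offset of the read's first sequenced base (base 0 of
        the original read), extrapolated across soft-clips in transcript
        space."""
        seg = min(segments, key=lambda s: s.query_start)
        gpos = seg.pos if seg.strand == "+" else seg.ref_end
        t = self.offset(gpos)
        if t is None:
            return None
        forward = seg.strand == self.strand
        return (t - seg.query_start) % self.J if forward else (t + seg.query_start) % self.J


def junction_context(
    coords: "RouteCoordinates",
    donor: int,
    acceptor: int,
    read_length: int,
    overhang: int = 10,
) -> Optional[JunctionContext]:
    """Geometry context for a genomic junction on a given isoform.

    The transcript-downstream exon starts at the acceptor on '+' isoforms and
    at the donor on '-' isoforms; its offset is the junction boundary b.
    Returns None when the junction does not lie on the isoform.
    """
    pos = acceptor if coords.strand == "+" else donor
    b = coords.offset(pos)
    if b is None or b <= 0:
        return None
    return JunctionContext(coords, b, read_length, overhang)


def pair_insert_span(
    pair_segments: Sequence[AlignmentSegment],
    coords: RouteCoordinates,
) -> Optional[int]:
    """Within-circle insert span K of a read pair on a given isoform.

    K is the transcript-space distance from the fragment's first base (on the
    transcript-forward read) to its last base (on the transcript-reverse
    read), taken modulo the circumference: the observed span when the
    fragment is assumed to wrap the circle zero extra times.
    """
    by_mate: Dict[int, List[AlignmentSegment]] = {}
    for s in pair_segments:
        by_mate.setdefault(s.mate, []).append(s)
    if len(by_mate) != 2:
        return None
    fwd = rev = None
    for segs in by_mate.values():
        if segs[0].strand == coords.strand:
            fwd = segs
        else:
            rev = segs
    if fwd is None or rev is None:
        return None
    t_start = coords.read_anchor_offset(fwd)
    t_end = coords.read_anchor_offset(rev)
    if t_start is None or t_end is None:
        return None
    return (t_end - t_start) % coords.J + 1


def collect_support_observations(
    fsj: FsjCandidate,
    pairs_by_id: Mapping[str, Sequence[AlignmentSegment]],
    coords: RouteCoordinates,
) -> List[Tuple[str, Optional[int]]]:
    """Per supporting pair of one junction: (strand label, within-circle K).

    The strand label says whether the junction-covering read runs
    transcript-forward ('fwd') or transcript-reverse ('rev'); K is None when
    the mate needed to place the fragment is missing.
    """
    obs: List[Tuple[str, Optional[int]]] = []
    for rid, (mate, seg_strand) in sorted(fsj.support_reads.items()):
        label = "fwd" if seg_strand == coords.strand else "rev"
        segs = pairs_by_id.get(rid)
        K = pair_insert_span(segs, coords) if segs else None
        obs.append((label, K))
    return obs


@dataclass
class PsiEstimate:
    """Raw and insert-length-corrected Psi for one AS event."""

    circ_id: str
    event_type: str
    member: Tuple[int, int]
    c1: int
    c2: int
    c_out: int
    psi_raw: Optional[float]
    psi_corrected: Optional[float]
    correction_applied: bool
    nested: bool = False
    incl_junctions: str = ""
    excl_junctions: str = ""

    def __post_init__(self) -> None:
        for v in (self.psi_raw, self.psi_corrected):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError("Psi must lie in [0, 1]")


def estimate_psi(
    circ_id: str,
    event_type: str,
    member: Tuple[int, int],
    c1_obs: Sequence[Tuple[str, Optional[int]]],
    c2_obs: Sequence[Tuple[str, Optional[int]]],
    c_out_obs: Sequence[Tuple[str, Optional[int]]],
    dist: Optional[InsertLengthDist],
    J_in: Optional[int],
    J_out: Optional[int],
    nested: bool = False,
    dominance_ratio: float = 10.0,
    ctx1: Optional[JunctionContext] = None,
    ctx2: Optional[JunctionContext] = None,
    ctx_out: Optional[JunctionContext] = None,
) -> Optional[PsiEstimate]:
    """Psi of one AS event from junction-support observations.

    ES uses psi = (c1 + c2) / (c1 + c2 + 2*c_out): c1 and c2 are two
    measurements (5' and 3' splice sites) of the single inclusion isoform
    while c_out is one exclusion junction.  A5SS/A3SS and IR compare one
    inclusion count (the longer form, passed as c1; c2 empty) against one
    exclusion count, psi = c1 / (c1 + c_out).  Corrected counts use the
    inclusion circumference J_in for c1/c2 and J_out for c_out.  Nested
    events (multiple independent groups, hence ambiguous circumference) are
    reported uncorrected.  Returns None when all counts are zero.
    """
    c1, c2, c_out = len(c1_obs), len(c2_obs), len(c_out_obs)
    if c1 + c2 + c_out == 0:
        return None
    two_sided = event_type == "ES"
    if two_sided:
        psi_raw = (c1 + c2) / (c1 + c2 + 2.0 * c_out)
    else:
        psi_raw = (c1 + c2) / (c1 + c2 + float(c_out))
    psi_corr = None
    applied = False
    if not nested and dist is not None and dist.usable and J_in and J_out:
        n1 = normalize_observations(c1_obs, J_in, dist, dominance_ratio, ctx1) if c1 else 0.0
        n2 = normalize_observations(c2_obs, J_in, dist, dominance_ratio, ctx2) if c2 else 0.0
        n_out = normalize_observations(c_out_obs, J_out, dist, dominance_ratio, ctx_out) if c_out else 0.0
        if None not in (n1, n2, n_out):
            denom = n1 + n2 + (2.0 if two_sided else 1.0) * n_out
            if denom > 0:
                psi_corr = min(max((n1 + n2) / denom, 0.0), 1.0)
                applied = True
    return PsiEstimate(
        circ_id, event_type, tuple(member), c1, c2, c_out,
        psi_raw, psi_corr, applied, nested,
    )


def linear_psi_from_mrna(
    fsj_support: Mapping[Tuple[str, int, int], set],
    chrom: str,
    inclusion: Sequence[Tuple[int, int]],
    exclusion: Sequence[Tuple[int, int]],
    covered: bool = True,
) -> Optional[float]:
    """mRNA-side Psi of an exon from all reads (no BSJ anchoring).

    ``fsj_support`` maps (chrom, donor, acceptor) to supporting read ids,
    collected from every read of a poly(A)+ alignment.  Same ratio as the
    circular estimate; an exon with inclusion junctions but no exclusion
    junction reads is constitutive (Psi = 1), one never expressed is absent
    (Psi = 0), and no junction coverage at all yields None.
    """
    inc = [len(fsj_support.get((chrom, d, a), ())) for d, a in inclusion]
    exc = sum(len(fsj_support.get((chrom, d, a), ())) for d, a in exclusion)
    inc_total = sum(inc)
    if inc_total + exc == 0:
        return None if covered else 0.0
    if len(inclusion) >= 2:
        return inc_total / (inc_total + 2.0 * exc)
    return inc_total / (inc_total + float(exc))


def _betabin_loglik(k: np.ndarray, n: np.ndarray, mu: float, s: float) -> float:
    a, b = mu * s, (1.0 - mu) * s
    return float(np.sum(special.betaln(k + a, n - k + b) - special.betaln(a, b)))


def _betabin_loglik_grad(k: np.ndarray, n: np.ndarray, mu: float, s: float):
    """Log-likelihood and its gradient w.r.t. the Beta parameters (a, b)."""
    a, b = mu * s, (1.0 - mu) * s
    l = float(np.sum(special.betaln(k + a, n - k + b) - special.betaln(a, b)))
    common = -special.psi(n + a + b) + special.psi(a + b)
    dl_da = float(np.sum(special.psi(k + a) - special.psi(a) + common))
    dl_db = float(np.sum(special.psi(n - k + b) - special.psi(b) + common))
    return l, dl_da, dl_db


_LOGIT_BOUND = 12.0
_LOG_S_BOUNDS = (np.log(1e-3), np.log(1e7))


def _fit_betabin(groups: List[Tuple[np.ndarray, np.ndarray]], shared_mu: bool):
    """Maximize the beta-binomial likelihood (logit/log parameterization,
    analytic gradients); returns (loglik, params)."""
    ks = [g[0] for g in groups]
    ns = [g[1] for g in groups]
    mus0 = [float((k.sum() + 0.5) / (n.sum() + 1.0)) for k, n in groups]
    pooled_mu = float(
        (sum(k.sum() for k in ks) + 0.5) / (sum(n.sum() for n in ns) + 1.0)
    )

    def unpack(x):
        if shared_mu:
            mus = [float(special.expit(x[0]))] * len(groups)
        else:
            mus = [float(special.expit(v)) for v in x[:-1]]
        return mus, float(np.exp(x[-1]))

    def neg_and_grad(x):
        mus, s = unpack(x)
        total = 0.0
        grad = np.zeros_like(x)
        for gi, ((k, n), mu) in enumerate(zip(groups, mus)):
            mu = min(max(mu, 1e-12), 1 - 1e-12)
            l, dl_da, dl_db = _betabin_loglik_grad(k, n, mu, s)
            total += l
            d_theta = (dl_da - dl_db) * s * mu * (1.0 - mu)
            d_logs = (dl_da * mu + dl_db * (1.0 - mu)) * s
            if shared_mu:
                grad[0] += d_theta
            else:
                grad[gi] += d_theta
            grad[-1] += d_logs
        return -total, -grad

    n_mu = 1 if shared_mu else len(groups)
    bounds = [(-_LOGIT_BOUND, _LOGIT_BOUND)] * n_mu + [_LOG_S_BOUNDS]
    best = None
    for s0 in (10.0, 100.0):
        if shared_mu:
            x0 = [special.logit(min(max(pooled_mu, 1e-5), 1 - 1e-5)), np.log(s0)]
        else:
            x0 = [
                special.logit(min(max(m, 1e-5), 1 - 1e-5)) for m in mus0
            ] + [np.log(s0)]
        res = optimize.minimize(
            neg_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, best.x


def betabinomial_diff_test(
    circ_in, circ_out, mrna_in, mrna_out
) -> Tuple[float, float]:
    """Likelihood-ratio test for different inclusion proportions.

    H0: one beta-binomial inclusion proportion shared by the circular and
    mRNA counts (dispersion free); H1: separate proportions, shared
    dispersion.  p from chi-square with 1 df.  Counts may be scalars or
    per-replicate arrays.  With a single observation per condition the
    dispersion is not identifiable and is fixed at the binomial limit
    (otherwise H0 can absorb any difference as overdispersion).  Fully
    degenerate counts (all-in or all-out in both conditions) return p = 1.
    """
    k1 = np.atleast_1d(np.asarray(circ_in, dtype=float))
    o1 = np.atleast_1d(np.asarray(circ_out, dtype=float))
    k2 = np.atleast_1d(np.asarray(mrna_in, dtype=float))
    o2 = np.atleast_1d(np.asarray(mrna_out, dtype=float))
    if np.any(k1 < 0) or np.any(o1 < 0) or np.any(k2 < 0) or np.any(o2 < 0):
        raise ValueError("counts must be non-negative")
    n1, n2 = k1 + o1, k2 + o2
    if n1.sum() == 0 or n2.sum() == 0:
        raise ValueError("each condition needs at least one observed read")
    all_in = o1.sum() == 0 and o2.sum() == 0
    all_out = k1.sum() == 0 and k2.sum() == 0
    if all_in or all_out:
        return (0.0, 1.0)
    if len(k1) == 1 and len(k2) == 1:
        stat = _binomial_lrt(k1[0], n1[0], k2[0], n2[0])
    else:
        groups = [(k1, n1), (k2, n2)]
        l0, _ = _fit_betabin(groups, shared_mu=True)
        l1, _ = _fit_betabin(groups, shared_mu=False)
        stat = max(0.0, 2.0 * (l1 - l0))
    return (stat, float(stats.chi2.sf(stat, df=1)))


def _binomial_lrt(k1: float, n1: float, k2: float, n2: float) -> float:
    def ll(k, n, p):
        p = min(max(p, 1e-12), 1 - 1e-12)
        return k * np.log(p) + (n - k) * np.log(1 - p)

    p0 = (k1 + k2) / (n1 + n2)
    l0 = ll(k1, n1, p0) + ll(k2, n2, p0)
    l1 = ll(k1, n1, k1 / n1) + ll(k2, n2, k2 / n2)
    return max(0.0, 2.0 * (l1 - l0))
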