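# Methods

## The problem

Circular RNAs (circRNAs) arise when a downstream splice donor is joined to
an upstream splice acceptor, producing a covalently closed transcript whose
hallmark in RNA-seq is the back-spliced junction (BSJ): reads crossing it
align *chiastically*, with their reference order inverted relative to their
query order.  Upstream callers report where circles begin and end, but not
what lies inside them.  `circexon` reconstructs the internal structure — the
exons a circle actually contains ("cirexons"), which need not coincide with
any annotated mRNA exon — and the alternative splicing among them, from
ordinary paired-end short-read data.

The central design choice is to treat the **BSJ read pairs as the primary
evidence**.  A read pair whose fragment crosses the BSJ provably comes from
the circle, so its split alignments document forward splice junctions (FSJs)
inside the circRNA without interference from the linear transcripts of the
same locus.  The price of this purity is paid twice: low-abundance circles
have few BSJ pairs (sensitivity), and BSJ pairs are *anchored* at the
junction, so they sample positions along the circle non-uniformly
(quantification bias).  The depth-based rescue and the insert-length
correction below address the two costs respectively.

## Detection

**FSJ detection.**  For every BSJ read pair, local alignment segments are
sorted by their position in the read; each query-adjacent pair of segments
on one chromosome and strand with a small query gap (<= 5 bases) and a
positive reference gap (1 base to 200 kb) votes for an FSJ.  Votes within
+-10 bp of each other are clustered, and the cluster is refined to the
placement of the canonical splice signal (GT..AG on the plus strand, CT..AC
as its reverse-complement image) with minimal shift from the
alignment-implied breakpoint, ties resolved leftmost.  Clusters with no
signal survive only with >= 3 supporting pairs.  Support always counts
distinct read pairs, never segments.

**Cirexon pairing.**  Splice acceptors (the circle's back-splice start plus
every FSJ acceptor) are paired with downstream donors (every FSJ donor plus
the back-splice end).  A candidate [a, d] is suppressed when a complete
refined FSJ lies wholly inside it — that junction splices the interior out,
contradicting one continuous exon — while a bare intervening acceptor or
donor (an alternative boundary) does not suppress, so equivalent cirexons
with alternative 5'/3' sites coexist.  Candidates longer than 10 kb are
never accepted on junction pairing alone.

**Depth refinement.**  When no BSJ pair covers an internal FSJ, the pairing
step emits a merged exon–intron–exon candidate.  Candidates fully tiled by
BSJ-pair segments are accepted outright.  Otherwise per-base depth from
*all* local alignments is tested for a discontinuity with a two-sided
Mann–Whitney U test on 50-base windows flanking each putative internal
boundary (refined FSJ sites from non-BSJ reads if any, else the position of
the largest depth step), alpha = 0.05; exact p for tie-free samples up to
20 per side, tie-corrected normal approximation otherwise.  A significant
step rejects continuity and triggers **rescue**: FSJs are recovered from
non-BSJ reads (including linear mRNA reads, which share the same splice
sites), junctions with a competitor sharing either splice site are excluded,
the survivors partition the candidate, and each sub-cirexon is depth-checked
once more.  Candidates that cannot be resolved are reported with evidence
`unresolved` rather than dropped.

**Routes and AS classes.**  Accepted cirexons and their FSJs form a DAG;
depth-first enumeration of all paths from the back-splice acceptor to the
donor yields the candidate circular transcripts (capped at 1000 routes,
flagged when truncated).  Exon skipping (ES): a cirexon strictly inside the
donor–acceptor span of a used FSJ; equivalent skipped cirexons are grouped.
Alternative 5'/3' splice site: two route cirexons sharing one boundary;
which label applies depends on the strand, and strand-unknown circles get
`A5SS/A3SS-unresolved` rather than a guess.  Intron retention: an FSJ whose
intron plus flanking cirexons are fully covered by BSJ pairs while the
spliced form coexists.  A circle with more than one independent group is
*nested*.

## Psi estimation and the insert-length correction

For an ES event, `psi_raw = (c1 + c2) / (c1 + c2 + 2*c_out)`: c1 and c2 are
BSJ pairs split-mapped to the two inclusion junctions — two measurements of
one inclusion isoform — while c_out counts the single exclusion junction,
hence its factor 2.  Alternative-site and IR events compare one inclusion
against one exclusion count one-sidedly.

Because BSJ pairs are anchored at the BSJ, the chance that a pair also
reaches a given junction depends on where the required fragment span falls
in the library's insert-length distribution P(K) — and, through the rolling
circle, on the isoform circumference J: a fragment exhibiting within-circle
span K may truly have insert length K + J·i for any wrap count i >= 0.  The
inclusion isoform always has the larger J, so fewer wrap terms fall inside
the insert distribution's support and raw Psi is *systematically
underestimated* — a bias that deeper sequencing cannot remove, only
re-measure.  Each junction's support count c is therefore normalized by the
total probability of its compatible insert lengths:

    c' = c / mean over compatible spans K of  sum_i P(K + J*i)

The compatible spans follow from the junction's transcript offset, the read
length and the minimal mappable overhang (10 bp): one read of the pair must
cross the BSJ (anchor window) while the other covers the junction (cover
window); every (anchor, cover) combination contributes one span, giving a
triangular weighting over a contiguous K range, evaluated per strand
configuration (junction covered by the transcript-forward or -reverse
read).  `psi_corrected` is the same ratio on normalized counts, with the
inclusion circumference for c1/c2 and the exclusion circumference for
c_out.  Under the simulator's sampling model this normalization is exactly
unbiased for the expected counts (each strand's normalized count estimates
the same per-event quantity).

**The c_max >> c_min branch.**  Some junctions are geometrically starved on
one strand: no insert length can link the anchor to the junction in that
direction, so its probability mass is nearly zero and a single stray pair
would be divided by it, exploding the normalized count.  Dominance is
therefore decided on the *expected* strand shares: when the mean compatible
probabilities differ by more than the dominance ratio (default 10), only
the dominant strand is used and doubled; otherwise both strands' normalized
counts are summed.  Both branches estimate the same quantity, so the branch
affects only variance.  When junction geometry is unavailable the rule
falls back to observed counts (`c_min = 0` or `c_max >= 10*c_min`), and the
normalization to per-pair Horvitz–Thompson weights 1/sum_i P(K_pair + J·i).
Circles with nested AS patterns have multiple circumferences and are
reported uncorrected.

P(K) is estimated from read pairs mapping fully inside exons >= 1000 bp that
are present with identical boundaries in every transcript of their gene; at
least 1000 such pairs are required, and the histogram is smoothed with a
sigma = 5 bp Gaussian kernel so that wrap sums are not dominated by
single-bin noise.  Without annotation the correction is disabled and
`psi_raw` is reported alone.

## The differential test

Skipped-cirexon inclusion in circRNAs is compared with the same exon's
inclusion in mRNA (junction counts from *all* poly(A)+ reads, no anchoring,
no correction; constitutive exons score 1, absent exons 0) by a
beta-binomial likelihood-ratio test: H0 one inclusion proportion shared by
both conditions with free dispersion, H1 separate proportions with shared
dispersion, p from chi-square with 1 df.  Fits use a logit/log
parameterization with analytic gradients (L-BFGS-B, deterministic
method-of-moments starts).  Two finite-sample facts are handled explicitly:

- With a single observation per condition the dispersion is not
  identifiable, and a free dispersion would absorb *any* difference
  (complete separation 50/0 vs 0/50 would yield p = 0.096).  The test
  therefore fixes dispersion at the binomial limit in that case, giving the
  closed-form binomial LRT (measured level 0.051 at counts near 100).
- The chi-square tail approximation converges slowly in the number of
  replicates for overdispersed counts: the statistic's mean is 1 but its
  95th percentile is ~4.4 at 8–100 replicates per condition (level
  0.056–0.057), reaching the nominal 3.84 only around 400 replicates
  (level 0.052).  The same tail appears with the dispersion fixed at its
  true value, so it is a property of the reference, not of the fit.  At few
  replicates the test is accordingly mildly liberal.

Benjamini–Hochberg FDR is reported alongside raw p, and |delta Psi| > 0.4
is flagged.

## The simulator

The simulator is first-class code that defines the package's study
conditions.  A synthetic mini-genome carries multi-exon genes (4–7 exons of
120–400 bp, introns 300–800 bp, half on each strand) whose every exon is
flanked by canonical splice signals, so any run of consecutive exons is a
plausible circle; twelve single-exon ~2 kb genes provide the constitutive
long exons the insert-length estimator needs.  circRNAs are runs of 2–4
consecutive exons (one per gene); ES circles need >= 3 exons and skip one
internal exon, with two isoforms at the assigned Psi.  Insert lengths come
from a two-component normal mixture sampled by the Box–Muller transform
from three uniforms; the four library presets are (mu=280, sigma=80),
(280/80 + 370/100 at 0.9), (mu=400, sigma=80) and (550/80 + 280/100 at
0.85), mixture mean 289 for the second.  Draws are untruncated at the
sampler level; fragment generation resamples lengths below the read length
(a pair must not read through itself), and the estimated insert
distribution is consistently that truncated law.  Fragments start uniformly
on the circle and wrap past the BSJ as often as their length requires
(rolling circle); pairs per isoform follow depth·J/(2·read length) scaled
by Psi.  Linear mRNA background is co-emitted at 10-fold exonic coverage,
providing both depth-test interference and the non-BSJ splice evidence the
rescue step uses.  The idealized SAM lists each read's true local
alignments as a perfect aligner with a 10 bp minimal segment would report
them, so the pipeline is testable without an external aligner; FASTQ output
allows a real aligner to be substituted.  What the generator does *not*
emulate: sequencing errors beyond uniform substitution (off by default),
PCR duplicates, mappability artifacts, repeats, expression-level variation
across genes, and non-uniform fragment-start bias — so passing tests
demonstrate algorithmic correctness under the stated sampling model, not
robustness to alignment noise on a real genome.

## Validation experiments and problem sizes

- **Detection sensitivity**: four PE100 libraries (one per insert preset),
  150–160 circRNAs at 25-fold circular depth, de novo BSJ calling plus full
  detection; cirexon boundaries scored at +-2 bp.  On idealized alignments
  both overall and BSJ-conditional sensitivity reach 100%; with a real
  aligner, mapping losses would reduce this.
- **Psi calibration**: the 3 true-Psi x 4 depth grid (0.25/0.5/0.75 x
  25–100x) with 50 replicate ES circles per cell.  Junction support is
  counted against the *truth* event structure (an estimator-calibration
  design: conditioning on de novo detection at Psi = 0.25 and 25x would
  measure detectability selection, not estimator bias; detection itself is
  validated separately).  The library distribution is taken from 200k
  sampled fragment draws, mirroring genome-wide estimation in a real
  library.  Raw Psi underestimates in every cell and the corrected
  estimate's bias is smaller in every cell (|bias| < 0.03 at 100x).
- **Calibration of the two tests**: 1000-replicate type-I error checks at
  alpha = 0.05 as described above.

Experiment sizes were chosen so the whole suite exercises every path at
comfortable statistical resolution on a single CPU.

## Known limitations

- IR events are quantified from read-through counts without insert-length
  correction (the retained isoform's geometry context is not built).
- The depth test at the maximal-step position is a selected-maximum test
  and is anti-conservative on noiseless data; on Poisson-like coverage the
  measured type-I error is nominal.
- Route enumeration caps at 1000 routes per circle; truncated circles are
  flagged and excluded from nothing else.
- The count normalization ignores hybrid configurations in which one read
  both crosses the BSJ and covers the junction; these require the junction
  to lie within a read length of the BSJ and are negligible for the exon
  sizes simulated here.
- Full-length isoform sequence reconstruction for nested AS patterns is out
  of scope.
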