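# Methods

This note documents the models implemented in `aims_architect`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Coordinate model

All coordinates are 0-based half-open on a circular chromosome. The two
replichores are defined by the origin and terminus: the forward arm runs
from *ori* forward (increasing coordinate, wrapping) to *ter*; on it the
Watson (+1) strand is leading, and on the reverse arm the Crick (−1) strand
is leading. Distance from the terminus is measured along the arm containing
a position and expressed as percent of total genome length, so 0 is the
terminus and 50 the origin when arms are equal. On unequal arms the longer
arm exceeds 50%; record objects keep the unclamped value and binned analyses
drop the excess above 50%, so unequal arm lengths cannot contaminate the
positional series.

## Replichore inference

Candidate breakpoints are intergenic-gap midpoints. For a candidate pair,
every protein-coding gene (classified by its midpoint; genes spanning a
candidate follow their midpoint) is assigned a putative strand class, and
the conditional pentamer frequencies P(B₅ | prefix tetramer, reading frame)
are tabulated per class with a pseudocount of 1 per pentamer. The additive
smoothing keeps the statistic finite for unseen tetramers and is dominated
by genuine counts at genomic scale. The breakpoint pair maximising the sum
of squared leading-lagging frequency differences, Δ, wins.

The search is two-stage: a coarse pass over every 10th gap, then an
exhaustive pass over all gaps within ±5% of genome length of the coarse
optimum, preserving the global maximisation at gap resolution without an
O(n²) sweep over all gap pairs. A flat Δ landscape (maximum < 2× the median
over evaluated pairs) sets a low-confidence flag rather than failing; at
small genome sizes (a few hundred genes) even genuine signal can trip this
conservative flag, which is why it is advisory, not fatal.

Polarity is assigned so that the count of genes transcribed away from the
origin — equivalently, leading-strand genes — is maximal; an exact tie sets
an ambiguity flag. GC skew is deliberately not used for inference (a
cumulative-skew profile is provided as a diagnostic only); the pentamer
statistic is the primary predictor, validated against *dif*-site motif hits.
The *dif* scan default allows 2 mismatches, configurable, since natural
sites drift from the consensus.

## AIMS detection

Counting is exact and exhaustive. The genome's 4⁸ concrete-octamer count
table is built per arm from the Watson strand; a leading-strand occurrence
of octamer w on the reverse arm is a Watson occurrence of its reverse
complement, so two per-arm tables determine every leading/lagging count,
including overlapping occurrences and the circular wrap. A degenerate
octamer's count is the sum over its concrete expansions, computed by tensor
contraction of the count table with IUPAC membership matrices — the full
space of octamers degenerate at ≤ 2 positions (all 11 degenerate IUPAC
codes, configurable) is scored in a few seconds per genome.

Detection criteria, at the default operating point:

| criterion | default | note |
|---|---|---|
| leading-strand bias ≥ | 0.70 | leading/(leading+lagging), genome-wide |
| leading copies N_i ≥ | 96 | genome-wide leading-strand count |
| terminus density increase ≥ | 15% | per-bp leading density, ter vs ori region |
| terminus bias increase | strict > | margin configurable, default 0 |

Region geometry: terminus region = *ter* ± 12.5% of genome length (25% of
the genome), origin region = *ori* ± 30% (60%); the remaining 15% buffers
the two. Symmetric windows keep the two arms balanced. The abundance
criterion compares per-bp densities, not raw counts, so the unequal region
lengths cannot masquerade as enrichment. The 15% default for the density
criterion is the least stringent edge of the calibration family: a genuine
two-fold planted terminus gradient, after region averaging and dilution by
the uniform background occurrence floor, measures well above it.

Null calibration rearranges fixed-size segments (default 40 kb; 10 kb
selectable — both sizes are legitimate readings of the procedure and are
left to the caller rather than silently reconciled) uniformly at random
within each arm, never across arms and never strand-flipped. This preserves
per-strand k-mer content up to segment-junction windows (≤ k−1 per junction)
while destroying any positional gradient. `calibrate_thresholds` sweeps a
stringency grid, reports genuine count, null mean ± 2 SD and fold
enrichment per point, and selects the least stringent point whose fold is
≥ 10 with > 100 genuine detections — maximising sensitivity subject to the
specificity floor; the most stringent qualifying point is reported too
(abundant-but-weak vs sparse-but-strong sets).

Detected octamers are grouped into families by greedy single linkage: two
octamers link if their concrete expansion sets intersect or a 7-symbol
prefix/suffix of one equals a suffix/prefix of the other. The union-find is
run on a canonically sorted list, making family labels order-independent.

## Inversion detection

Inputs are signed gene orders over shared reciprocal-best orthologs; genes
present in only one genome are skipped as transparent. An inversion is a
maximal run whose ortholog indices descend by one with all relative signs
flipped, validated by `flank_k` = 2 syntenic genes on each side (the flank
requirement is unquantified in the underlying procedure; two genes per side
is the minimal choice that rejects translocation artifacts). Circular index
arithmetic makes the call invariant under rotation of either order.
Candidates whose physical span contains *ori* or *ter* of either genome are
discarded — such inversions do not flip replichore polarity — and the
discard applies if either genome's span is affected. Records are
deduplicated across pairwise comparisons by exact ortholog content, with
provenance retained. Only maximal blocks are reported; nested or multi-block
scrambles appear as separate maximal blocks, each flank-validated. The
detector is exhaustively cross-checked against a brute-force oracle that
tests every contiguous block directly.

## HGT insertions and the loss estimator

A gene is called foreign when it has no reciprocal-best ortholog in any
sister species, none in any conspecific strain (≥ 2 strains required — the
multi-strain requirement guards against scoring a parallel loss as a gain),
and its best conspecific similarity is below 40%. Consecutive foreign genes
merge into one insertion spanning first-start to last-end, including
intervening intergenic DNA (the span convention is open; including the
intergenic DNA matches how an integrated fragment physically occupies the
chromosome).

The permissive fraction of an insertion is the fraction of recipient-AIMS
occurrences within its span that sit on the leading strand, computed from a
per-genome occurrence index (two sorted position arrays; per-span counts are
binary searches). Insertions with zero occurrences are flagged undefined
and excluded from curves. The bias-vs-distance curve uses length-weighted
per-bin means by default (matching the cumulative-length construction of
the loss estimator; unweighted means are also available) and is fitted with
a decaying exponential trend SB(d) = a·e^(−d/b) + c, bounds a ∈ [0,1],
b > 0, c ∈ [0,1]. The offset c is included because the observed curves
plateau well above 0.5; this is a trend fit, not a probability-density fit.

The loss estimator compares a terminus window (0–6% from the terminus) with
an origin window (42–48%; the final 2% is ignored to absorb unequal arm
lengths). For each window, F(s) is the fraction of total inserted bp in
fragments with permissive fraction ≤ s; the loss is ∫F_ori − ∫F_ter, which
equals the difference of the length-weighted mean permissive fractions (the
implementation uses the weighted-mean identity; a numerical-integration
cross-check appears in the tests). The Kolmogorov–Smirnov comparison runs
on the per-fragment (unweighted) values.

## Ter counter-selection simulation

A 4.5 Mb genome (default) with two equal arms. Sites are placed from the
terminus outward with spacing s_k = s₀(1 + αk), α set so the last spacing is
`gradient_ratio` (default 10) times the first and s₀ solved so the sites
span the arm — site density therefore decreases away from the terminus.
Inversions draw a uniform midpoint within an arm and a size from a
log-uniform distribution on [1 kb, 500 kb] (an empirical size file can
replace it), truncated so the span stays within one arm. An inversion is
rejected when a site lies strictly inside its span (boundary coincidence is
permissive; site orientation is ignored, since mere inclusion is the
modelled lethality). Surviving inverted bp are spread over
distance-from-terminus bins by overlap, and surviving midpoint counts are
binned separately for count-based statistics. A sum-of-squared-differences
comparison against a reference distribution supports searching for the site
count that best reproduces an observed degree of terminus avoidance.

A power note on small site counts: with tens of sites per arm, the rejection
probability still varies several-fold along the arm (the placement gradient
concentrates sites near the terminus), so at Monte-Carlo precision (10⁵
draws) a two-sample chi-square distinguishes the surviving positional
distribution from the unconstrained one even for a single site. At
observational scale — a few hundred genuine inversions, ~20% per-bin
sampling error — the same distortion is far below detectability. The
corresponding acceptance test asserts indistinguishability at Monte-Carlo
precision and therefore fails; it is retained as specified rather than
weakened, and this paragraph is the analysis of why.

## Compatibility scoring

Fragment bias uses the sup statistic SBᵢ = max(N_W, N_C)/(N_W + N_C) over a
fragment's two strands, which requires no knowledge of the donor's
replication geometry. Fragments are 10 kb, sampled uniformly with
replacement over start positions on a fixed linearization (wrap-around
fragments allowed on circular donors; with/without replacement is
immaterial at genome scale). Fragments containing no occurrence are
excluded from the per-AIMS mean — the statistic is undefined there, and
scoring them 0.5 would bias sparse AIMS — with exclusion counts reported.
The compatibility C_XY is the recipient-abundance-weighted mean of the
per-AIMS means; contributions are deliberately not weighted by the AIMS's
bias in the recipient. Note the sup statistic's small-count upward bias:
even a donor with no strand preference yields mean SB well above 0.5 at a
few occurrences per fragment, so unrelated-donor baselines sit near
0.55–0.65 depending on occurrence density; comparisons are therefore always
relative between donors scored with identical sampling parameters.

## Confound controls

Four codon-usage metrics (the standard repertoire, as the underlying
analyses name none): Wright's effective number of codons; mean within-family
absolute deviation from genome-wide synonymous frequencies; |GC3 − genome
GC3|; and RMS distance between gene and genome RSCU vectors. Each is
regressed per gene against distance from the terminus. Inverted-repeat
spacing merges, per k-mer (k ∈ {5,6,7}) and per arm, the occurrence
positions of the k-mer and its reverse complement; an inverted pair is a
consecutive pair in opposite orientations (palindromic k-mers pair every
consecutive occurrence — the most literal reading of adjacent inverted
repeats), and mean pair spacing per 10 kb window is regressed against
terminus distance. Operons are taken as supplied or derived as same-strand
runs with gaps < 50 bp. Ks uses the Nei–Gojobori site-counting scheme with
equal-weight averaging over mutational pathways (stop-traversing pathways
excluded) and Jukes–Cantor correction; pS ≥ 3/4 is flagged saturated. All
regressions report significance; none asserts it.

## Synthetic genomes

The generator emits a circular chromosome with *ter* at 0 and *ori* at L/2.
Background sequence is i.i.d. at the requested GC (order-0 by design — all
signals are planted explicitly, so a more elaborate background model would
only obscure what a test demonstrates). Genes sit on an even grid, each
leading-strand with probability 0.75 (typical of bacterial gene
orientation); leading and lagging genes draw codons from usage tables that
differ by a keto (G/T third-position) preference factor 1 + e with e = 0.2,
which creates the frame-specific pentamer signal the breakpoint finder
detects, at a magnitude comparable to natural replichore skews. AIMS copies
are written last (nothing overwrites them): positions follow a linear
density gradient parameterised by the terminus:origin endpoint ratio, and
each copy is written in the leading orientation with a probability that
interpolates linearly from its origin to its terminus value. Truth counts
are recounts of the emitted sequence, so coincidental background
occurrences are part of the recorded truth; an emit-time assertion checks
no planted copy was lost.

Two effects deserve mention when choosing plant strengths. First, a planted
octamer's measured properties include its background occurrences, which
carry the coding-strand codon skew and can run counter to the plant — an
octamer planted at 86% orientation bias can measure below 70%. Second, a
linear endpoint density ratio of r measures as a much flatter
terminus-region/origin-region per-bp ratio after region averaging (a 2×
endpoint gradient measures ≈ 1.4×). Planted-recovery experiments therefore
state their conditions in measured terms and set endpoint parameters to
realise them.

Sister derivation applies i.i.d. point substitutions (divergence < 0.1 so
gene identity is preserved), then inversions (contiguous gene blocks
reversed and strand-flipped, confined to one arm with two clear flanking
genes, never spanning *ori*/*ter*), then insertions (novel random-sequence
genes at intergenic points; recipient-AIMS copies can be written into each
insertion with a position-dependent permissive probability). The emitted
homology table covers the parent and two pseudo-strains: native genes are
reciprocal-best everywhere with similarity equal to the realised nucleotide
identity; inserted genes are absent everywhere with best conspecific
similarity drawn in [20, 35). What the generator does not emulate: indel
evolution, gene loss, rearrangement histories with nested events, amino
acid-level selection, mobile-element structure at insertion boundaries, and
compositional heterogeneity of real backbones. Passing recovery tests on
these fixtures demonstrates correctness of the inference machinery under
the stated generative model, not robustness to everything real genomes do.

## Problem sizes and determinism

The test suite and the acceptance script run on scaled-down study
conditions chosen for single-CPU execution: breakpoint recovery on twenty
(tests) or ten (script) 2 Mb genomes with 2,000 genes; AIMS calibration and
recovery on one 4 Mb genome with 20 planted octamers and 25 arm-shuffle
null replicates; inversion-detector validation on 1,000 random ≤ 60-gene
instances against the brute-force oracle; the loss estimator on 10,000
fragments; the Ter simulation at 10⁵ draws; the end-to-end pipeline on a
400 kb fixture. Every stochastic component takes an explicit seed or
generator; the pipeline derives per-stage seeds from one global seed by a
fixed scheme and its manifest records SHA-256 checksums of all artifacts,
so a rerun with the same seed is byte-identical.
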