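# Methods

## Problem and model

Retroviral insertional-mutagenesis (IM) screens identify candidate cancer
genes as clusters of insertions recurring across independent tumours.
Because enhancers act over large genomic distances through chromatin
looping, insertions that deregulate one gene can be dispersed over several
linearly distal but spatially proximal loci. `clichunter` detects such *3D
hotspots*: pairs of insertion clusters (ICs) on the same chromosome whose
mutual Hi-C contact significantly exceeds the contact expected at their
genomic distance — co-localized insertion clusters (CLICs).

The pipeline assumes intra-chromosomal Hi-C contact maps that are already
corrected for experimental biases (GC content, restriction-site density,
mappability); only the genomic-distance effect is handled here.

## Rank-based distance normalization

Contact frequency decays steeply with genomic distance and the score
distributions at different distances are neither Gaussian nor
homoscedastic, so an expected-by-distance ratio is a poor normalizer.
Instead every score h_ij is replaced by a distance-conditional rank.  For
each superdiagonal k of the symmetric matrix (all bin pairs at distance
k·bin_size) a pool H^d is assembled; each entry of the k-th superdiagonal
becomes its average-tie rank within its pool, divided by the pool size,
giving a normalized score in (0, 1].

Short superdiagonals near the matrix corner are extended with whole
neighbouring superdiagonals, appended in the order k−1, k+1, k−2, k+2, …
until the pool holds at least L values.  This is justified by the contact
distributions at neighbouring large distances being nearly exchangeable.
Two choices here are this package's own, since the pooling contract leaves
them open:

* **whole superdiagonals are appended, never truncated** — the pool may
  overshoot L, and ranks are divided by the actual pool size.  This avoids
  an arbitrary rule for which elements of a partially included
  superdiagonal to keep, and keeps scores comparable across distances;
* **the alternation starts one distance below k** — symmetric in
  expectation and deterministic.

The default L is twice the bin count of the longest chromosome in the run
(`L="auto"`), matching the pooling depth used at genome scale; any explicit
L may be passed.  The main diagonal carries a NaN sentinel and is excluded
from every downstream statistic.  Two consequences define the method's
contract and are enforced by tests: the output is invariant under any
strictly monotone transform of the raw scores, and the per-distance mean of
normalized scores is ~0.5 for every distance whose pool is its own
superdiagonal (for distances whose pools are dominated by neighbours the
head mean is biased toward the neighbours' scale — inherent to pooling, and
the reason extended pools are only used where the data run out).

## Chromatin compartments

The plaid pattern of the normalized map is summarized by the first
principal component of the bin-by-bin correlation matrix of normalized
contacts (eigenvector of the largest eigenvalue).  The sign of PC1
partitions bins into the two compartments.  The global sign of an
eigenvector is arbitrary, so it is oriented to correlate positively with
per-bin total normalized contact, a proxy for the open (A) compartment;
when both compartments have exactly equal total contact — possible in
perfectly symmetric synthetic plaids — the orientation is not identifiable
and the partition alone is meaningful.  Bins with no contact variance are
masked (NaN in the track).  A map with no within-distance variation at any
distance (e.g. constant) is rejected as degenerate.

## Insertion clusters

Insertions are smoothed with an unnormalized Gaussian kernel,
f(x) = Σ_i exp(−(x−p_i)²/2σ²), with 2σ = 80 kb and a 10 kb evaluation grid
(σ/4, fine enough for bin-accurate peaks at 40 kb; the evaluation window is
±8σ, truncation error < 1e-13).  Because the kernel is not area-normalized
an isolated insertion contributes a peak of height exactly 1, so peak
heights read as "effective overlapping insertions" and the median-peak
threshold is interpretable.

ICs are strict local maxima of f.  The extent of an IC is the package's own
contract (only the bin alignment of boundaries is externally prescribed):
the interval between the two flanking local minima of f, **trimmed inward
to where f stays above min(0.5, peak/2)**.  The un-trimmed flanking-minima
rule lets extents run across long stretches of near-zero density whenever
the background is sparse, producing loci with no insertion support; the 0.5
floor (half of one insertion's kernel contribution) pins extents to the
region actually covered by insertions while the peak/2 fallback keeps
sub-threshold peaks well-defined.  Boundaries are then aligned outward to
the nearest bin boundary, and extents under three bins are expanded by one
bin on both sides (so a CLIC test always has ≥ 3×3 = 9 positive values).
Overlapping extents are kept separate, never merged.

ICs are split at the genome-wide **median of peak heights over detected
peaks** (strictly above = high-scoring).  Computing the median over peaks
rather than over all grid values of f is a deliberate reading of an
ambiguous rule; the all-values alternative would be dominated by the
near-zero baseline and make essentially every IC "high".

Bin categories for the genome-wide co-localization overview use 200 kb
bins (the typical scale of a common insertion site): non-inserted (S=0),
inserted (0<S≤N_m, default N_m=2), recurrently inserted (S>N_r, default
N_r=5).  Counts in the gap (N_m, N_r] belong to no category and are
excluded from category statistics.

## CLIC detection

For two disjoint ICs with n and m bins, the *positive distribution* is the
n×m block of normalized scores bridging them; the *negative distribution*
pools all superdiagonal scores at bin distances in [d_min, d_max] (the
range spanned by the positive pairs), widened one distance at a time —
alternating below d_min and above d_max, clipped at the chromosome — until
it holds at least L values.  The positive entries themselves are excluded
from the negative distribution so planted or real signal cannot dilute its
own null.  A one-tailed Wilcoxon rank-sum test (positive > negative) gives
the raw p-value; because inputs are ranks, the whole test is invariant
under monotone transforms of the raw Hi-C scores.

The rank-sum test enumerates the exact null when both samples have fewer
than 10 values and no cross-sample ties, otherwise it uses the
tie-corrected normal approximation without continuity correction; each
result records which branch was used.  All intra-chromosomal pairs of
high-scoring ICs form the testing family; Holm's step-down controls the
family-wise error rate, and a pair is significant when its adjusted
p-value is at most the family level α (default 1e-5, matching the scale of
a genome-wide screen; the synthetic-data studies below use α=0.05, the
level at which the FWER calibration is actually testable with hundreds of
replicates).

## Downstream statistics

* **Mutual exclusion** — the mean-Manhattan distance between two loci is
  the fraction of all samples in which exactly one of the two binary
  occupancy indicators is 1 (the literal normalized Manhattan distance
  between binary vectors; denominators restricted to inserted samples are
  a documented alternative reading, not implemented).  CLIC pairs are
  compared against non-significant high-IC pairs with a two-sided rank-sum
  test.
* **Enrichment** — all overlap questions (CIS genes, cancer-census genes,
  TFBS carriers, high- vs low-scoring IC interactions) reduce to a 2×2
  cross-classification within a universe, tested with Fisher's exact test
  (two-sided); degenerate margins are flagged rather than silently
  accepted.
* **TFBS carriers** — an IC carries transcription-factor binding sites if
  its peak count per bp (peaks counted by midpoint containment) strictly
  exceeds the median density over all ICs.
* **Expression association** — for a gene in CLIC locus A, T^A is the
  Welch t-statistic comparing expression between samples with and without
  insertions in A, and T^AB the same with the carrier group widened to
  insertions in A or in the partner locus B.  Welch's unequal-variance form
  is used because carrier groups are small and variance heterogeneity is
  expected.  The spatial association score is sign(T^A)·(T^AB − T^A):
  positive when distal insertions amplify the local effect.  When B is
  never inserted the groupings coincide and T^AB = T^A exactly; when
  T^A = 0 the score is reported as |T^AB| with a zero-sign flag.

## Synthetic data

The generator produces, per call, one chromosome with:

* **Contact map** — expected contact (|i−j|+1)^(−γ) (γ=1 by default, the
  canonical intra-chromosomal decay), multiplied by `compartment_contrast`
  (default 2) when both bins fall in the same alternating compartment block
  (deterministic blocks, default 25 bins, so compartment tests have exact
  ground truth), with mean-one multiplicative log-normal noise (log-sd
  `noise_dispersion`, default 0.3) drawn on the upper triangle and
  mirrored.  Log-normal noise keeps the matrix positive and exercises the
  rank normalization under heteroscedasticity.
* **Insertions** — per sample a Poisson(`background_rate`) number of
  uniform background insertions (default 5; the real screen's background
  fraction is unknown, so this is a free parameter chosen to give
  realistically noisy IC calling, not an estimate), plus selected clusters:
  each spec hits `expected_hits` distinct samples, one insertion each,
  placed N(center, width/4).  For a planted CLIC pair with exclusivity e, a
  fraction e of the samples hitting both clusters is moved out of one of
  them (alternately), with replacement samples drawn outside the pair so
  hit counts are preserved; e=0 leaves the hits independent and e=1
  forbids co-occurrence.
* **Planted contacts** — the A×B contact block of each planted pair is
  multiplied by its boost factor.  The planted locus spans ±3 placement-sd
  around the cluster center, i.e. the region that actually contains the
  cluster's insertions; a narrower locus would plant a signal
  geometrically inconsistent with the insertion cloud it is meant to
  explain.
* **Expression** — one gene per planted locus plus filler genes; expression
  is effect_size × 1[sample carries an insertion in the locus or its
  planted partner] + N(0, noise_sd).

What the generator does **not** emulate: TADs and loops, inter-chromosomal
contacts, non-uniform integration preference (TSS tropism), copy-number
structure, sample-specific insertion burdens, or correlated gene
co-expression.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not performance on real
screens.

## Study sizes and numerical choices

The simulation studies in the test suite and `scripts/acceptance.py` use
problem sizes chosen to give stable rates with fast turnaround: 250–500-bin
chromosomes (10–20 Mb at 40 kb), cohorts of 100 tumours, 4–32 planted
clusters of 25–40 hits, contact boost 5, and 20–200 replicates per rate.
The false-positive calibration and the planted-pair recovery study run
with `compartment_contrast=1`: under a plaid pattern two selected clusters
sharing a compartment are *genuinely* co-localized relative to a
distance-matched mixed-compartment null, so an "all-null" genome with
plaid does not exist.

Tie handling is average-rank throughout; threshold comparisons
("exceeding" a median or threshold) are strict.  Degenerate inputs raise
typed errors (constant maps, zero-variance expression, empty categories)
rather than returning NaNs.  All randomness flows through
`numpy.random.default_rng` seeded from explicit integer seeds; a fixed
seed reproduces every output byte-for-byte.

## Known limitations

* The IC boundary rule (flanking minima with a density floor) is one of
  several defensible contracts; boundary-sensitive results (TFBS density,
  gene-to-locus assignment) should be checked for robustness to it.
* Holm over the full family is conservative when thousands of dependent
  pairs are tested; the paper-scale α=1e-5 on adjusted p-values is very
  strict at desk scale.
* The negative distribution excludes the positive entries; with extremely
  long ICs on short chromosomes this can leave too few background values,
  which raises an error instead of degrading silently.
* Mean-Manhattan uses all samples in the denominator, which compresses
  distances for rarely inserted loci.
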