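# Methods

This note documents the models and procedures promcoloc implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Coordinates and interval logic

All internal coordinates are 0-based half-open (BED-native). GTF input
(1-based inclusive) and printed heterochromatin spans (1-based inclusive,
genome-browser style) are converted on read; everything is written back in
BED convention. Overlap requires at least one shared base by default
(`min_overlap=1`, configurable); half-open adjacency is not overlap.

Multi-set peak union (`merge_union`) forms connected components of the
overlap graph: merging is transitive, so peaks A and C that never directly
overlap still join one region when both overlap B. This matches the union
behaviour of the standard R peak-overlap tooling and differs from
pairwise-only intersection — combination counts therefore count merged
regions by default, with a peak-unit mode for users who want Venn counts in
original peak units. For `min_overlap > 1`, intervals shorter than the
minimum can never connect and are emitted as singleton regions; region spans
are then not guaranteed disjoint (they are for the default of 1).

## Promoter annotation

Promoters are symmetric, strand-independent windows of ±`halfwidth` bases
around the TSS, inclusive on both sides (401 bp at the default halfwidth of
200). The peak anchor is the summit when one is available (the point-source
estimate peak callers emit) and the interval midpoint otherwise; the anchor
mode is configurable. Features are assigned in priority order — promoter
beats gene body beats intergenic — using the simplified three-label scheme
appropriate when only gene spans are known. A peak anchored inside several
overlapping promoter windows goes to the gene with the nearest TSS, with
distance ties broken toward the lexicographically smaller gene id, so output
is deterministic regardless of input order. For multi-TSS genes the
annotation uses whatever gene-level TSS the input provides; isoform-level
TSS selection is out of scope.

The euchromatin/heterochromatin partition is a fixed per-chromosome
coordinate map. The built-in dm6 map contains the pericentromeric blocks of
the five large chromosome arms (2L:22000975–23513712, 2R:1–5398184,
3L:22962476–28110227, 3R:1–4174178, X:22628490–23542271, given 1-based
inclusive). Membership is tested at the anchor point, inclusive of the block
start.

## Motif model

A PWM over ACGT is built from a count matrix with a pseudocount:
probs[i,a] = (counts[i,a] + c) / (rowsum + 4c); scores are log2 odds against
a background distribution (uniform by default — the scanning background is
configurable because published scanners do not always document theirs).
Zero-probability letters at pseudocount 0 receive a −100 log-odds sentinel,
which sinks any word containing them below any realistic threshold while
staying on the quantization grid.

P-values are exact over a discretized score grid: per-position scores are
quantized to integer multiples of `step` (default 1e-3 score units) and the
distribution of the total word score under the background model is obtained
by dynamic-programming convolution. The threshold for a target p-value is
the minimal grid score t with P_bg(score ≥ t) ≤ p. Scanning quantizes window
scores with the same step, so a window passes exactly when the DP counted
its word — for motif lengths up to 8 this is verified against exhaustive
enumeration of all 4^L words, and halving the step does not change which
words pass except at genuine grid boundaries. Windows containing N are
skipped rather than scored as background, to avoid inflated hits in masked
regions. Both strands are scanned by default; minus-strand hits (scored with
the reverse-complement PWM) are reported at the plus-strand coordinate of
the window start. The word p-value is defined per strand; with both strands
scanned a peak is flagged when any window on either strand passes. With
multiple PWMs, per-peak flagging is a logical OR, each PWM at its own
threshold.

## Monte Carlo colocalization test

For bound sets A and B (sizes N1, N2) within a housekeeping-promoter
universe U, the observed statistic is the sharing fraction
Fo = k / |A ∪ B| = k / (N1 + N2 − k), k = |A ∩ B|. The phrase "ratio of
shared ids to all ids in the sets" is ambiguous between |A ∪ B| and
N1 + N2 as the denominator; both are strictly monotone in k, so p-values are
identical either way and only the reported Fo value differs. The Jaccard
form is the default because it is the standard set-similarity measure.

The null draws `n_samples` (default 5000) independent pairs of uniform
random subsets of sizes N1 and N2 from U — each subset without replacement
internally, the two subsets independent of each other — and records their
sharing fractions Fs. Subset draws use a partial Fisher–Yates shuffle
vectorized across samples. The empirical p-value is the proportion of Fs
strictly exceeding Fo (the literal "exceeded" definition); `greater_equal`
and add-one ((r+1)/(n+1)) options exist because an exact zero p-value is
statistically awkward. The universe is an explicit input — typically the
housekeeping-gene promoter list — and is never defaulted, since it defines
the null.

Because Fo is strictly increasing in k, the null law of k is the
hypergeometric distribution of the intersection of two uniform fixed-size
subsets, and `hypergeom_tail` (exact P(X > k)) serves as an independent
closed-form oracle: the Monte Carlo p converges to it, and the test suite
asserts agreement within three Monte Carlo standard errors on a parameter
grid. P-values across all protein pairs are Benjamini–Hochberg adjusted
(step-up). Each pair gets its own RNG substream derived from the master seed
and the sorted pair names, so adding a protein to the panel never perturbs
the other pairs' results.

### Calibration of the literal estimator

The strict-exceedance p-value is mildly anti-conservative on this discrete
null. Rejecting when P(X > k_obs) ≤ α rejects all k_obs ≥ k0 with k0 the
smallest k whose strict tail is ≤ α, and the resulting size is
P(X ≥ k0) = P(X > k0 − 1) > α. At the calibration study's conditions
(|U| = 1000, marginals 0.1, so N ≈ 100), the exact size at α = 0.05 —
marginalized over N1, N2 — is 0.0697; the `greater_equal` variant's size is
0.0363. The package default stays with the literal definition because that
is the procedure being reproduced; users who need a valid (conservative)
p-value should set `tie_rule="greater_equal"` with `smoothing="add_one"`.
The acceptance-level calibration check, which asserts the nominal 99%
binomial band [0.032, 0.068] around 0.05, accordingly fails under the
default estimator by this exact margin — a property of the estimator, not a
sampling defect; the same machinery passes the oracle-agreement check
everywhere and the power check is monotone with rejection rates reaching 1
at θ = 8.

## Synthetic-data generator

The generator emulates exactly the structure the colocalization analysis
assumes: binary binding per housekeeping promoter with controlled marginals
and controlled pairwise dependence.

- **Gene models.** Each chromosome is split into equal slots, one gene per
  slot; the TSS is uniform within the slot interior and the span (slot/3
  long) extends downstream. Adjacent TSSs are therefore always more than
  2 × 200 bp apart, promoter windows never overlap, and annotation can
  recover bound sets exactly. Exactly round(fraction × n_genes) genes are
  flagged housekeeping (default fraction 0.6, in the range reported for
  promoter-bound architectural proteins). The default heterochromatin map
  is a pericentromeric block covering the first 15% of each chromosome,
  mimicking the arm-proximal blocks of real assemblies.
- **Binding indicators.** Pairwise dependence is parameterized by the odds
  ratio θ = (p11·p00)/(p10·p01) of a bivariate Bernoulli; p11 is the
  Plackett root of the quadratic in the marginals, checked against the
  Fréchet bounds (infeasible combinations error out naming the bound).
  θ = 1 yields independence. With more than two proteins, the others are
  drawn conditionally on the first (reference) protein — only
  reference–other odds ratios are controlled, higher-order structure is
  whatever that construction induces, and the ground truth records the
  realized odds ratios for every pair. This pairwise scheme is sufficient
  to exercise a pairwise test; it does not emulate three-way interactions.
- **Peaks and sequences.** Each bound gene gets one peak centered on its
  TSS (default width 200) with an optionally jittered summit; jitter up to
  min(halfwidth, width/2 − 1) preserves exact recovery, larger jitter only
  warns. Genome sequence is i.i.d. from the PWM background; selected peaks
  receive one PWM-sampled word at a uniform offset and strand, recorded in
  the ground truth. Implants in overlapping peaks can overwrite each other;
  recovery oracles condition on the implant surviving in the final
  sequence. Defaults (1000 genes, two chromosomes of 1 Mb, marginals 0.1)
  are the conditions used by the calibration and power studies.
- **Not emulated:** read-level ChIP-seq (fragments, coverage, peak-calling
  noise), spatial peak structure beyond the promoter, RNA-seq counts, and
  higher-order binding dependence. Passing tests therefore demonstrate
  correctness of the downstream logic under the model's assumptions, not
  robustness to upstream peak-calling artifacts.

## Expression link

`de_overlap_summary` takes a DE table (gene, log2FC, FDR; significance at
FDR < 0.05 by default) and a caller-supplied gene → stratum map (the package
deliberately stays agnostic about whether strata are defined by any peak or
by motif-containing peaks). Empty strata report NaN means, not zeros; a
significant gene with log2FC exactly 0 counts in "all DE" but in neither
direction. qChIP enrichment is the ratio of percent-input at the target to
percent-input at the positive control region; replicate vectors return
per-replicate ratios with mean and SD. DE model fitting itself is consumed,
not reimplemented.

## Problem sizes and determinism

The test-suite and acceptance studies use 1000 genes, 5000 Monte Carlo
resamples per pair, 1000 calibration replicates and 200 power replicates per
θ — sizes at which the binomial error bands quoted above are meaningful
while a full run completes in a few minutes on one CPU. All randomness flows
from explicit seeds through named numpy Generator substreams
(SeedSequence-derived), so every pipeline output is bit-identical across
runs with the same config, and per-stage streams are independent.
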