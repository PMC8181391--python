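# Methods

## Scope and model

`atacatlas` implements the desk-side half of a multi-tissue bulk ATAC-seq
analysis: peak calls and fragment intervals come in (one BED each per
sample), and the package produces the standard peak atlas, the normalized
peak × sample matrix, entropy-based tissue-specificity calls, TSS
enrichment / region-composition QC, and a motif × tissue enrichment
matrix. Upstream steps (trimming, alignment, duplicate filtering, peak
calling) are explicitly out of scope; fragments are consumed as BED
intervals, and converting a coordinate-sorted BAM is a documented upstream
step (`bedtools bamtobed`).

### Coordinates and interval semantics

All coordinates are 0-based half-open (BED). Two intervals overlap iff
they share ≥ 1 bp; intervals that merely touch are neither "overlapping"
nor merged. This matches the default semantics of BedTools, the tool
family these file formats come from. 1-based inputs are not auto-detected.

### Replicate reproducibility

A tissue's retained peaks are those of replicate 1 that overlap (≥ 1 bp)
any replicate 2 peak. This is the operative presence-in-both-replicates
rule; the full irreproducible-discovery-rate copula model is deliberately
not implemented — the overlap rule is transparent, deterministic, and
testable against planted replicate-private noise. Which replicate's
coordinates survive is a genuine free choice; replicate 1 (first listed)
is the reference, and a symmetric variant (`mode="union"`) merges the
surviving intervals of both replicates. Filtering happens per tissue
first, then the merge across tissues builds the standard peak set.

### TSS distance and region classes

Distance from a peak to a TSS point is unsigned: 0 if the TSS lies within
[start, end), otherwise the gap to the nearest peak boundary (start − pos
on the left, pos − end on the right). Ties are broken by the first TSS in
(chrom, position, gene) sorted order so output is deterministic. A peak is
promoter-proximal iff distance ≤ `proximal_cutoff` (default 2,000 bp — a
conventional promoter window, configurable, never hard-coded in logic).
Peaks on chromosomes without any TSS get an undefined distance, are
classed distal, and are tallied separately as "unassigned" rather than
entering the region-class fractions.

### Counting and normalization

Counting follows BedTools `intersect -c`: a fragment adds 1 to every
standard peak it overlaps, so a fragment spanning k peaks counts k times.
RPM(p, s) = raw(p, s) × 10⁶ / library_size(s), where the library size is
the total number of fragments in the sample's file (the stand-in for
"mapped reads"), not reads-in-peaks. The log view is log₁₀(RPM + 1); the
pseudocount (default 1) is configurable because a pure log of zero is
undefined. Sample correlation is Pearson on the log matrix over **all**
atlas peaks (correlation precedes specificity calling); clustering is
average linkage on distance 1 − r. A constant (zero-variance) sample gets
NaN sentinels and a warning rather than a fabricated correlation.

### Entropy specificity index

For peak p with per-tissue accessibility Eᵢ (replicate **mean** RPM;
`sum` and `max` are offered since replicate aggregation is a free choice):

  Rᵢ = Eᵢ / ΣE,  H = −Σᵢ Rᵢ log₂ Rᵢ,  0·log₂0 := 0.

H ∈ [0, log₂ N]. The sum runs over all N tissues — an index bound that
excluded the endpoints would contradict the stated range. Calling is
strict: specific iff H < threshold; a peak exactly at the threshold is not
specific. Specific peaks are assigned to argmaxᵢ Rᵢ with ties resolved to
the first tissue in sorted name order. Peaks with ΣE = 0 (possible after
asymmetric replicate filtering) cannot be scored; they are flagged
undefined and excluded from calling. Body-organ and brain-region analyses
run as separate invocations over their own tissue sets with their own N
and threshold (3 and 2 bits respectively at reference scale); cortex
sub-regions can be collapsed into one tissue through the analysis's
`merge` mapping. `entropy_distribution_report` summarizes the H histogram
and the valley between its two dominant modes to document a threshold
choice; it never applies one.

### TSS enrichment

Per TSS, fragment coverage is binned over ±`half_width` (default 2,000 bp,
bin 10 bp), flipped for minus-strand TSSs, averaged over TSSs, and divided
by the mean of the outer `flank` (default 100 bp) bins on each side. The
score is the normalized value at the TSS bin. A fragment contributes 1 to
every bin it overlaps — the same ≥ 1 bp semantics as peak counting.
Uniform coverage scores exactly 1 by construction. Zero flank coverage
makes the ratio undefined: the score is reported as a sentinel (None) with
a warning. The window/bin/flank convention is an implementation choice
(ENCODE-style); no authoritative parameterization exists for this metric.

### Motif enrichment

A PWM (JASPAR plain-text counts, probabilities after a 0.5 matrix
pseudocount) scores windows by Σ log₂(p/background) on both strands;
windows containing N never hit; a position hit on both strands counts
once. The hit threshold defaults to 60 % of the motif's maximum achievable
log-odds. A sequence is motif-positive at ≥ 1 hit. For each
(motif, tissue), P is the one-sided hypergeometric upper tail of the
foreground positives among the pooled foreground + background sequences.
Background defaults to the non-specific atlas peaks, subsampled to 5× the
largest foreground with a seeded generator. P-values are raw — no
multiple-testing correction is applied, since the matrix is a ranking
device (top-15 per tissue; ties broken by motif id). This module is a
transparent stand-in for HOMER-style known-motif enrichment: no GC-matched
background, ZOOPS scoring, or de novo discovery.

## The synthetic world

The simulator states one explicit generative model:

* **Design**: `n_tissues` × `n_replicates` (default 10 × 2), 200 shared
  peaks and 200 specific peaks per tissue (defaults), width 500 bp, laid
  on a slot grid with 2,000 bp gaps over 5 × 2 Mb chromosomes, labels
  shuffled across slots.
* **Accessibility**: weight 1 everywhere except a specific peak's home
  tissue, which gets `specific_fold` (default 8). Each sample's fragment
  counts are one multinomial draw of `fragments_per_sample` (default 10⁶)
  over (background, peaks) with background probability
  `background_fraction` (default 0.4) — so RPM is exactly the right
  depth correction. At fold 8 with 10 tissues the expected profile of a
  specific peak has H ≈ 2.68 bits (below the 3-bit cutoff) while shared
  peaks sit at log₂ 10 ≈ 3.32 (above it): the planted design and the
  threshold are jointly coherent by construction.
* **TSSs**: one per shared peak, at its center (so shared peaks are
  promoter-proximal and carry the TSS enrichment signal); specific peaks
  are > 2 kb from any TSS at default spacing.
* **Peak calls**: the true peaks with Gaussian boundary jitter
  (σ = 20 bp, clipped so both replicates always keep the true center ⇒
  true peaks always survive the both-replicates filter), plus
  replicate-private noise peaks at 10 % of the true count per replicate,
  placed in inter-peak gaps — the failure mode the reproducibility filter
  exists to remove.
* **Sequence**: i.i.d. uniform A/C/G/T background; one instance of the
  home tissue's motif (8-mer PWM, consensus probability 0.97) planted in
  80 % of specific peaks at center ± a uniform offset, sampled from the
  PWM. At the 60 % log-odds threshold this PWM requires an exact consensus
  match, giving ≈ 78 % detection of planted instances against ≈ 1.5 %
  background-positive sequences — chosen once from this power analysis,
  not tuned against test outcomes.
* **Determinism**: all randomness flows from named substreams spawned
  from one seed, so identical config + seed gives byte-identical files,
  and skipping genome synthesis never perturbs the counts.

Two generation routes share one distribution. The counts-only route draws
per-peak counts without materializing fragment coordinates; the file route
additionally places each counted fragment entirely inside its source peak
and each background fragment entirely inside an inter-peak gap, so
counting the emitted fragment files against the true peaks reproduces the
multinomial draw exactly (asserted in the suite on a jitter-free config).
Statistical tests at full depth (10⁶ fragments × 20 samples × 20 seeds)
use the counts-only route; materializing those fragment files would be
hundreds of gigabytes of text for no additional information.

**What the simulator does not emulate** — and therefore what a green test
does not establish: realistic fragment-length mixtures and nucleosome
periodicity, Tn5 sequence bias, GC-content structure (background is
uniform, so motif-enrichment power on GC-skewed genomes is untested),
mappability artifacts and blacklist regions, correlated replicate noise,
and peak-width heterogeneity. Tests against this world validate the
*mechanics and statistics* of the pipeline, not its behavior on any
particular real genome.

## Numerical choices and degenerate inputs

* Entropy is computed in double precision with 0·log₂0 := 0; it matches a
  compensated-summation oracle to 1e−12 and is exactly permutation- and
  scale-invariant.
* Thresholds must lie in (0, log₂ N); configuration validation enforces
  this and collects all errors in one pass.
* Malformed BED lines raise a parse error naming the 1-based line number.
* An empty fragment file yields an all-zero column plus a warning; a zero
  library size is an error naming the sample.
* scipy's average-linkage implementation is deterministic for a fixed
  input; equal-distance merges resolve by cluster index. Permuting sample
  order permutes leaves but leaves cophenetic distances unchanged (tested).
* Hypergeometric tails come from `scipy.stats.hypergeom` and are verified
  against exhaustive enumeration on pools ≤ 30.

## Known limitations

* The reproducibility filter is pairwise; > 2 replicates are folded left
  to right (rep1 vs rep2, result vs rep3, ...).
* Fragments spanning two merged peaks are double-counted by design
  (BedTools semantics); with merged peaks and short fragments this is
  rare but means column sums can in principle exceed in-peak fragment
  counts.
* The motif stage scores presence/absence per sequence; hit multiplicity
  within a sequence is ignored (as in a ZOOPS-like reading).
* TSS enrichment uses a single aggregate profile per sample; no per-TSS
  dispersion is reported.
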