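# Methods

This note documents the models, parameter choices and numerical conventions
behind `ampliedit`, and what the synthetic-data generator does and does not
emulate.

## Editing-rate model

The editing rate at a catalog site is defined as

```
rate = G / depth
```

where `depth` counts reads that (i) passed the alignment-identity filter,
(ii) cover the site with an aligned, non-gap base, and (iii) carry a base
quality ≥ 20 (inclusive) at that position. The denominator is therefore
*per-site*, not per-sample: under quality filtering the per-site depth is the
only well-defined denominator, and for a 100-nt amplicon nearly every read
covers every site anyway. `N` bases count toward depth (they are tracked in
their own field) but never toward G or A.

The 95% interval is the Wilson score interval, chosen over Clopper–Pearson
for its better behaviour at the extreme rates this assay meets (near 0 at
the detection limit, near 0.8 in highly edited tissues). Zero-depth sites
yield a flagged missing estimate, never a division by zero.

**Error floor and detection.** The background substitution rate is measured
per sample as the pooled non-reference base fraction across the catalog's
non-editable control positions (N excluded on both sides); when no control
has depth the default floor of 0.001 (0.1%) applies. Detection of editing at
a site is a one-sided exact binomial test of the G count against the floor;
a call requires `p < alpha` (default 0.01) *and* a rate strictly above the
floor, so a rate exactly at the floor is never a detection.

## Alignment

Reads are aligned semi-globally — the read end-to-end, the reference locally
— under match +1, mismatch −1 and affine gaps where a gap of length L costs
−(3 + L) (open −3, extend −1). Both orientations are tried; ties prefer the
forward read. The DP engine is `Bio.Align.PairwiseAligner`, configured to
exactly this scheme (free end gaps only on the reference side); the test
suite verifies score equality against an independently written Gotoh DP on
hundreds of random instances, including all-random low-identity pairs.

With a single amplicon reference, mapping quality in the multi-mapping sense
is undefined. The read-level reliability filter is instead the alignment
identity (matching bases / read length), default threshold 0.8; it plays the
same contractual role as a minimum-mapping-quality cutoff: discard reads
that do not clearly originate from the amplicon.

## Demultiplexing

Reads carry an i5 barcode in their first 8 nt and an i7 barcode in their
last 8 nt. A read is assigned to the unique sample minimizing the *combined*
Hamming distance over both indices, if that minimum is ≤ `max_mismatch`
(default 1 — a deliberate, conservative default; the combined budget is
stricter than per-index budgets). Distance ties go to an AMBIGUOUS bin and
out-of-tolerance reads to UNASSIGNED, so assigned + unassigned + ambiguous
always equals the input read count and no read is ever guessed into a
sample. An exact-match dictionary fast path handles the error-free majority;
the scan path is checked against a brute-force nearest-neighbour oracle in
the tests.

## Splice-donor scoring

A donor site is the 9-mer of the last 3 exonic plus first 6 intronic bases.
Two models are provided:

* **Maximum-entropy model** (score5ss table dialect): score =
  log2(consensus-factor × me2x5[idx]) where the consensus factor covers the
  near-invariant G(+1)/T(+2) positions against a fixed genomic background
  (A/T 0.27, C/G 0.23) and `me2x5` is the trained 4^7-entry table of
  probability ratios over the remaining 7 positions, indexed base-4
  (A<C<G<T). The trained table cannot be re-derived at desk scale and is an
  external data dependency (`data/maxent5/`); the loader validates size,
  positivity and finiteness and records a SHA-256 checksum.
* **PWM fallback**: sum over positions of log2(f/background) using canonical
  mammalian donor consensus frequencies (MAG|GTRAGT-style), with a small
  pseudocount. It is additive by construction, preserves the qualitative
  ranking of editing variants (each A→G edit at a consensus-A position
  weakens the site), and is explicitly flagged
  `comparable_to_maxent = False`.

Variant enumeration substitutes G at each subset of the declared editable
adenosine offsets (2^k variants, unedited first). Only the two editable
positions of the Flnb junction (9-mer offsets 1 and 6) are modeled for the
bundled fixture. Ranking is by descending score with deterministic
tie-breaks (fewer edits first, then lexicographic) and a tie flag.

## Synthetic-data generator

The generator is the package's study-conditions model, not a test prop. Per
sample it draws:

* **depth** ~ NegativeBinomial(mean 7,824, size 10). The mean is the median
  per-sample coverage of the emulated assay; the size parameter encodes the
  wide observed spread of per-sample coverage in multiplexed runs.
* **editing states**: three sites (S/G, Q/R, intron+4) per molecule, by
  default independent with marginals (0.35, 0.85, 0.5) — the adult-brain
  regime where pre-mRNA Q/R editing exceeds 80% — or an explicit 8-state
  joint for linkage studies.
* **splicing**: `P(spliced | state) = logistic(λ0 − λ1·QR − λ2·in4)` with
  defaults λ0 = 1.0, λ1 = 2.5, λ2 = 1.0, chosen so the spliced pool's Q/R
  rate falls near 0.55 when the pre-mRNA rate is 0.85 (the observed
  pre-/mRNA contrast). `expected_pool_rates` gives the closed-form pool
  rates by 8-state enumeration; the test suite re-derives them with an
  independent oracle.
* **reads**: i5 + amplicon + i7, single-end over the full insert (the read
  layout of the emulated run is not fixed by the assay; single-end is the
  simulator's declared convention and the demultiplexer only assumes the
  barcode layout). Substitution errors are applied at mean rate e = 0.001,
  per-base proportional to 10^(−q/10) of the drawn Phred quality (Gaussian
  around −10·log10(e), sd 3, Phred+33), rescaled so the realized mean error
  is exactly e; errors pick one of the three other bases uniformly.

Deliberate non-features: indels, PCR duplicates/jackpotting, chimeras,
index hopping, position-dependent error ramps (hook provided but off by
default), and intron removal in spliced reads — spliced and unspliced
molecules are sequenced over the same amplicon coordinates, with the spliced
flag driving pool membership only. Consequently, passing tests demonstrate
correctness of the quantification given the substitution-error model; they
do not probe indel robustness or pre-mRNA/mRNA amplicon differences in real
libraries.

**Counts-level shortcut.** Estimator-recovery and error-floor studies
(hundreds of samples at depth 7,824) sample per-site base counts directly
from the same multinomial error model (`simulate_site_counts`) instead of
pushing ~4M reads through FASTQ, demultiplexing and alignment. The
read-level path is validated separately by exact truth comparison on
error-free samples (per-site counts equal the simulator's per-read truth)
and by the binomial-interval checks; the two paths share the identical error
parameterization. Study sizes used by the acceptance script (500 recovery
samples, 96 × ~40 reads demultiplexing, 200k molecules for selection, a
24-sample end-to-end study at depth ~800) were chosen as the smallest sizes
at which the Monte-Carlo error is far below the effects being measured.

## Other numerical conventions

* Coordinates are 0-based half-open internally; all reported genomic
  positions are 1-based. Editing is defined on the transcript strand, so the
  catalog stores transcript-strand bases plus a strand flag for genomic
  mapping (on the bundled fixture the transcript runs with the + strand).
* The bundled `flnb_synthetic` reference is a synthetic 100-nt sequence —
  labeled as such — that preserves the real inter-site geometry (S/G 7 nt
  upstream of Q/R; intron+4 5 nt downstream; donor context CAG|gtgagg) and
  carries three non-editable control adenosines for floor estimation. The
  100 nt are treated as the biological insert, excluding adapter tails.
* Aggregation uses the n−1 standard deviation; single-replicate groups
  report sd 0 with an explicit flag (keeps tissue tables rectangular);
  groups whose replicates are all missing are dropped with a log entry.
* ΔCt expression is 2^(−(Ct_target − Ct_ref)); the editing–expression fit is
  ordinary least squares with R² reported, and a zero-variance predictor
  returns a flagged undefined fit.
* The maturation odds ratio is [m/(1−m)] / [p/(1−p)] for mRNA rate m and
  pre-mRNA rate p; degenerate rates (0 or 1) yield a clamped, flagged value
  (|log10 OR| ≤ 6) rather than infinity.
* Sanger peak-ratio estimates accept heights or areas alike — the caller
  labels the input; G/(A+G) with both peaks zero is missing.

## Known limitations

* Maximum-entropy donor scores require the external trained tables; the PWM
  fallback ranks variants but its absolute scores are not comparable.
* The aligner is substitution- and gap-aware but editing calls are not
  indel-aware (an indel over a site simply removes that read from the
  site's depth).
* The error floor is pooled across control positions and assumes
  position-uniform errors; sequence-context-specific error structure is not
  modeled.
* Detection power at rates within ~2× of the floor depends strongly on
  depth; the binomial test is exact but the floor itself is estimated, and
  its sampling error is not propagated.
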