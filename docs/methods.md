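# Methods

This note records the model, the parameters that matter, what the synthetic
data does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Signature extraction (`io_align`)

Coordinates are 0-based half-open everywhere inside the package; conversion
to VCF's 1-based convention happens only at VCF read/write boundaries.

Intra-alignment signatures are `I`/`D` CIGAR operations of length
≥ `min_sig_len` (default 50 bp, the SV size floor) taken from primary
alignments with MAPQ ≥ 20. Secondary alignments are ignored; supplementary
alignments contribute only to split-read signatures. Inter-alignment
signatures come from read-adjacent segment pairs of one read, with segment
read-offsets mirrored for reverse-strand segments so all segments of a read
share one read axis. Pair classification precedence: different chromosomes →
translocation breakpoint evidence (never imaged); discordant orientation →
inversion segments; reference overlap → duplication segments; otherwise a
reference-gap/read-gap imbalance beyond `min_delta` (50 bp) → one DEL or INS
fragment. All fragment lists are sorted (start, end, read id) so extraction
is byte-reproducible.

Region depth is the mean per-base count of primary, non-duplicate alignments
over the region, rounded to two decimals. It feeds the stack height, which is
how images are normalized across coverages.

## Encoding (`encoder`)

Defaults: α = 10 000 bp (caps the worst-case INV window at 2α per side),
image 128×128 px, stack-height factor 1.0. The test suite and the acceptance
script configure 64×64 or 32×32 images; these are problem-size choices for
desk-scale runs — the network and encoding are size-agnostic as long as both
dimensions are divisible by 8 (three 2×2 pools).

Channel predicates (containment, midpoint, length) are evaluated on the
fragment's *true* extent even when the drawn portion is clipped to the
region; clipping only affects pixels. A fragment for which no rule fires
encodes no variant feature and is not drawn at all — drawing it would occupy
a stack row with black-on-black pixels and silently displace informative
fragments when the stack is full. Stack packing is first-fit: fragments in
sorted order take the lowest row where their column span is free; when every
row is occupied the remainder are dropped deterministically. Two-window INV
regions are drawn side by side with a one-bin black separator.

Nearest-neighbour resampling was chosen because it preserves the exact
{0, 255} channel alphabet; any interpolating resize would fabricate
intermediate intensities that the encoding rules never produce. A
consequence worth knowing: at depth 1 the single canvas row is stretched over
the full image height, so "one read" and "all reads agree" look alike in the
row dimension — depth, not row count, carries the coverage information, by
design.

## Callset handling (`callset`)

Multi-caller merging collapses same-type records within 1 kb whose length
ratio is ≥ 0.7; the survivor takes member-wise median position/length and the
union of caller names. The merge is greedy over sorted records, hence
deterministic and idempotent. Candidate labeling uses the same two
thresholds (refdist 1000 bp, pctsize 0.7) with best-by-distance one-to-one
assignment; evaluation reuses the identical matcher so training labels and
reported precision/recall cannot disagree with each other.

TRA records are canonically ordered breakpoint pairs. Merging is greedy
single-linkage under the same-event predicate (equal chromosome pairs, both
breakpoint offsets ≤ γ = 1000 bp), processing records in sorted order and
comparing against the running member-median representative; clusters with
support from ≥ c₀ = 2 distinct callers survive. c₀ = 2 is the weakest
non-trivial consensus. Greedy and transitive-closure clustering coincide when
events are separated by well over γ, the regime the thresholds target; on
adversarial chains (records spaced just under γ apart) they can differ, as
any fixed-radius clustering must.

VCF output is version 4.2 with `SVTYPE`, `END`, `SVLEN`, `SUPPORT` INFO
fields. Translocation mates are written as `CHR2` + `POS2` rather than
abusing `END`: htslib clamps an `END` smaller than `POS`, which silently
corrupts mates on lexicographically earlier chromosomes. `CHR2`+`END` input
from other callers is still accepted.

## Mislabel elimination (`mislabel`)

ω = 256 makes the per-pixel code `R·ω² + G·ω + B` a collision-free 24-bit
colour integer; the column sum over rows is therefore invariant to stack
order (a property of the formula, verified by test). Flattening is applied to
the post-resize fixed-size image so every sample yields the same feature
length. PCA keeps 10 components (deterministic full SVD, sign fixed by
making the largest-magnitude loading positive); k-means uses k = 8 per SV
type with 10 restarts and a fixed seed. A cluster "contains incorrectly
labeled samples" when its positive fraction is ≥ 0.5 — the majority reading;
negatives in such clusters are removed, positives never are, labels are never
flipped. The threshold, k, and component count are configurable; clustering
runs per SV type because feature scales differ across types. Per-type class
balancing caps are 5000/5000/10000/10000 (INS/DEL/INV/DUP), applied as
seeded uniform down-sampling per class.

## Classifier (`model`)

Three convolution blocks (3×3 kernel over the 3 input channels — read as a
2-D spatial kernel on RGB input, not a volumetric one), ReLU, 2×2 max-pool,
then two fully connected layers each followed by dropout (0.5) and a single
sigmoid unit. Widths default to 16/32/64 conv channels and 256/64 FC units;
tests use 8/16/32 and 64/32, again a scale choice. Training is binary
cross-entropy on the logit (numerically stable softplus form) with Adam
(lr 1e-3, β = 0.9/0.999), batch 64, and a seeded held-out split whose AUC is
tracked per epoch; the best-AUC parameters are what the checkpoint stores.
All randomness (split, batch order, dropout masks, init) flows from one seed,
so training is bit-reproducible. The network is implemented directly in
numpy (im2col-free convolution as nine shifted matrix products, explicit
backward passes); at these model sizes a tensor runtime is unnecessary and
single-core training takes seconds to minutes.

Filtering keeps a candidate iff its score is strictly greater than 0.5; a
score of exactly 0.5 is dropped. One model per SV type is the default, since
the evidence geometry differs per type.

## Synthetic data (`simulate`)

The simulator synthesizes alignment records directly on a reference
coordinate space — no bases, no read simulator, no aligner. Reads tile each
contig at the target coverage (default 30×, read length 12 ± 1.5 kb,
haploid carriers by default with a heterozygous option); reads spanning a
truth event with ≥ 150 bp flanks carry its signature: a `D`/`I` op (INS
lengths jittered, σ = 8 bp), forward/reverse/forward split segments for INV,
two overlapping forward segments around the tandem junction for DUP, and
cross-chromosome split pairs for TRA. The longest piece of a split read is
the primary alignment, as an aligner would report it. Match stretches are
salted with sub-threshold (< 50 bp) indels at a low per-base rate as noise.

Default event lengths are 60–600 bp (DEL/INS), 0.6–4 kb (INV), 1–5 kb
(DUP). The INV/DUP floors are set by the geometry of the encoding rules:
split segments are read-half sized, so a duplication much shorter than the
read length produces segments that fail every channel predicate and encode
to an empty image — real callsets show the same effect, which is why
callers report such events from clipped, shorter segments that this
simulator does not model.

Decoys (false candidates) come in two kinds: type-labeled records at
signature-free loci, and "corrupted coordinate" copies of real events
displaced far beyond both the matching radius and the source event's split
segments (wrapping around the contig when the event region is crowded). Both
are constructed to violate the labeling rule, so planted labels are exactly
recoverable — the cross-module consistency the tests assert.

What the simulator does not emulate: base-level sequencing error, mapping
ambiguity, repeat-mediated mismapping, diploid phasing, nested or adjacent
overlapping events, and aligner-specific clipping behaviour. Tests passing
on this data show the pipeline's mechanics (signature handling, encoding
geometry, label plumbing, learnability of cleanly separable classes), not
performance on real genomes; negatives here are far easier than the
hard negatives real callers emit.

## Scale choices in tests and the acceptance script

Learnability is demonstrated with 500 positives + 500 negatives per type
(32×32 images, 8 epochs); end-to-end filtering on an independent 30× dataset
of 100 events + 60 decoys; the acceptance script uses 200 + 210 per type for
training. These sizes run in tens of seconds on one core while leaving the
class-separation structure intact.

## Known limitations

* TRA candidates are never imaged or CNN-filtered, only distance-merged —
  a stated boundary of the encoding.
* The mislabel purity rule is one admissible operationalization
  (majority-positive clusters); it is configurable because other readings
  exist.
* Greedy TRA clustering can split chains that transitive closure would join
  (see above).
* Checkpoints store raw weights; there is no calibration beyond the fixed
  0.5 decision rule.
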