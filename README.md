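# svsieve

**svsieve** filters merged long-read structural-variant (SV) callsets. SV
callers built on long reads (Sniffles, PBSV, SVIM, cuteSV, …) disagree with
each other, and merging their outputs buys sensitivity at the price of many
false positives. svsieve encodes the alignment evidence around each merged
candidate — insertions (INS), deletions (DEL), inversions (INV) and
duplications (DUP), each ≥ 50 bp — into a fixed-size three-channel image and
lets a small convolutional network decide whether the candidate is a real
variant. Translocations (TRA), which live at the breakpoint level, are not
imaged; they are merged across callers by a breakpoint-distance rule and kept
when enough callers agree.

It is aimed at people running multi-caller SV pipelines on PacBio/ONT data
who want consensus callsets with higher precision without giving up the
recall the merge bought them.

## Method

**Encoding.** For a candidate with breakpoints *bpt_left*, *bpt_right* and
length *svl*, alignment evidence is collected in a search region:
`[bpt_left − svl, bpt_right + svl]` for DEL/DUP, `[pos − svl, pos + 2·svl]`
for INS, and for INV either the same window (*svl* ≤ α) or two
breakpoint-flanking windows `[bpt_left − α, bpt_left + α/2]`,
`[bpt_right + α/2, bpt_right + α]` when *svl* > α (default α = 10 kb).
Evidence fragments come from `I`/`D` CIGAR operations ≥ 50 bp (INS/DEL) and
from split-read segment pairs: a reference gap exceeding the read gap by
> 50 bp (DEL), the converse (INS), overlapping segments (DUP), and
orientation-discordant segments (INV). Each fragment gets binary RGB
channels — for INS/DEL/DUP, B = 255 iff the fragment lies completely inside
the region, G = 255 iff its midpoint falls between the breakpoints, R = 255
iff its length is < 2·*svl*; for INV, B marks split-read evidence and R marks
orientation discordance, with G as before. Fragments are stacked into rows
sized by the local read depth and the canvas is resampled (nearest neighbour)
to a fixed image size, so any event length at any coverage yields the same
input shape.

**Training.** Candidates are labeled against a truth set (same type, within
1 kb, length ratio ≥ 0.7, one-to-one). Because truth sets are incomplete,
some "false positives" are real variants; to purge them, images are flattened
per column, `ArrE[i][j] = Σ_k (R[k][j]·ω² + G[k][j]·ω + B[k][j])` with
ω = 256, PCA-reduced, k-means clustered, and negatives landing in
majority-positive clusters are removed. After per-type class balancing, one
classifier per SV type is trained: three 3×3 conv + ReLU + 2×2 max-pool
blocks, two fully connected layers with dropout, and a sigmoid output,
minimizing binary cross-entropy (numpy implementation, Adam).

**Detection.** A candidate is kept iff its score is strictly greater
than 0.5. TRA records T_a, T_b are the same event iff their chromosome pairs
match and |Pos_a1 − Pos_b1| ≤ γ and |Pos_a2 − Pos_b2| ≤ γ (γ = 1000);
clusters supported by ≥ c₀ callers (default 2) are emitted. Results are
scored as Pre = TP/(TP+FP), Rec = TP/(TP+FN), F1 = 2·Pre·Rec/(Pre+Rec).

## Worked example

svsieve ships a simulator that synthesizes alignments with embedded SV
signatures plus truth and decoy VCFs, so the whole pipeline runs without any
external data:

```
$ svsieve simulate --out simdemo --seed 4 --coverage 30
90 events, 60 decoys -> simdemo/alignments.bam

$ svsieve evaluate --calls simdemo/decoys.vcf --truth simdemo/truth.vcf
TYPE      TP    FP    FN    Pre%    Rec%     F1%
DEL        0    15    30    0.00    0.00   undef
DUP        0    15    15    0.00    0.00   undef
INS        0    15    30    0.00    0.00   undef
INV        0    15    15    0.00    0.00   undef
All        0    60    90    0.00    0.00   undef
```

The decoy callset matches nothing in the truth set (zero precision and
recall; F1 is reported as undefined rather than 0 when a denominator
vanishes). Training on candidates labeled against the truth set and
filtering a fresh dataset is the two-stage pipeline:

```
svsieve train  --bam train/alignments.bam --vcf caller0.vcf --vcf caller1.vcf \
               --truth train/truth.vcf --out model/ --seed 1 --image-size 64
svsieve detect --bam detect/alignments.bam --vcf caller0.vcf --vcf caller1.vcf \
               --model-dir model/ --out detect_out/ --seed 1 --image-size 64
```

`train` writes one checkpoint per SV type, an audit TSV of the negatives the
mislabel step removed, and a per-epoch loss/AUC log. `detect` writes a single
sorted VCF with `SVTYPE`, `END`, `SVLEN` and `SUPPORT` INFO fields and a
provenance block (seed, config hash) in the header.

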