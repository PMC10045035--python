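"""Alignment-signature extraction from BAM/SAM files.

Long reads expose structural-variant evidence in two ways: *intra-alignment*
signatures (``I``/``D`` operations inside one CIGAR string) and
*inter-alignment* signatures (one read split into a primary plus supplementary
segments whose spacing, overlap or orientation on the reference is
inconsistent with a contiguous read). This module turns both into
:class:`SignatureFragment` objects that the encoder can draw, and computes the
local read depth used to size the read stack.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pysam

# CIGAR operation codes (BAM spec): M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_QUERY_CONSUMES = {0, 1, 4, 7, 8}
_REF_CONSUMES = {0, 2, 3, 7, 8}

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_SIG_LEN = 50


@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned segment of a (possibly split) read.

    ``read_start``/``read_end`` are offsets on the *original* read, i.e. for a
    reverse-strand segment the soft/hard-clip lengths are mirrored so that
    segments of one read are comparable on a single read axis.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    is_reverse: bool
    is_supplementary: bool
    mapq: int

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(f"empty reference span {self.ref_start}..{self.ref_end}")
        if self.read_start >= self.read_end:
            raise ValueError(f"empty read span {self.read_start}..{self.read_end}")


@dataclass(frozen=True)
class SignatureFragment:
    """One drawable piece of SV evidence.

    For insertions the fragment is anchored at the insertion locus and its
    span equals the inserted length — a synthetic interval used only for
    drawing, not a real reference interval.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    sig_type: str  # INS | DEL | INV_SEG | DUP_SEG
    source: str  # cigar | split
    orientation_discordant: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"fragment start {self.start} > end {self.end}")
        if self.source == "cigar" and self.orientation_discordant:
            raise ValueError("cigar-sourced fragments cannot be orientation-discordant")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TraEvidence:
    """Cross-chromosome split-pair breakpoint, canonically ordered."""

    read_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int


@dataclass(frozen=True)
class RegionCoverage:
    chrom: str
    start: int
    end: int
    depth: float


def _fragment_sort_key(f: SignatureFragment) -> tuple:
    return (f.start, f.end, f.read_id)


def extract_cigar_fragments(
    bam: pysam.AlignmentFile,
    chrom: str,
    region_start: int,
    region_end: int,
    min_len: int = DEFAULT_MIN_SIG_LEN,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[SignatureFragment]:
    """Collect I/D CIGAR operations of length ``>= min_len`` anchored in the region.

    Deletions span the deleted reference interval; insertions are anchored at
    the insertion locus with a span equal to the inserted length. Secondary
    and supplementary alignments are ignored (supplementaries contribute via
    :func:`extract_split_fragments` instead). Output is sorted by
    (start, end, read_id).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    fragments: list[SignatureFragment] = []
    for aln in bam.fetch(chrom, region_start, region_end):
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        if aln.mapping_quality < min_mapq:
            continue
        ref = aln.reference_start
        for op, length in aln.cigartuples or []:
            if op == 1 and length >= min_len and region_start <= ref < region_end:
                fragments.append(
                    SignatureFragment(aln.query_name, chrom, ref, ref + length, "INS", "cigar")
                )
            elif op == 2 and length >= min_len:
                if ref < region_end and ref + length > region_start:
                    fragments.append(
                        SignatureFragment(aln.query_name, chrom, ref, ref + length, "DEL", "cigar")
                    )
            if op in _REF_CONSUMES:
                ref += length
    fragments.sort(key=_fragment_sort_key)
    return fragments


def segment_from_alignment(aln: pysam.AlignedSegment) -> AlignmentSegment:
    """Build an :class:`AlignmentSegment` with read offsets on the original read axis."""
    cig = aln.cigartuples or []
    left = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
    right = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
    aligned_query = sum(l for op, l in cig if op in (0, 1, 7, 8))
    if aln.is_reverse:
        read_start = right
    else:
        read_start = left
    return AlignmentSegment(
        read_id=aln.query_name,
        chrom=aln.reference_name,
        ref_start=aln.reference_start,
        ref_end=aln.reference_end,
        read_start=read_start,
        read_end=read_start + aligned_query,
        is_reverse=aln.is_reverse,
        is_supplementary=aln.is_supplementary,
        mapq=aln.mapping_quality,
    )


def collect_segments(
    bam: pysam.AlignmentFile,
    chrom: str,
    region_start: int,
    region_end: int,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> dict[str, list[AlignmentSegment]]:
    """Group primary + supplementary segments overlapping the region by read id."""
    by_read: dict[str, list[AlignmentSegment]] = {}
    for aln in bam.fetch(chrom, region_start, region_end):
        if aln.is_unmapped or aln.is_secondary:
            continue
        if aln.mapping_quality < min_mapq:
            continue
        by_read.setdefault(aln.query_name, []).append(segment_from_alignment(aln))
    for segs in by_read.values():
        segs.sort(key=lambda s: s.read_start)
    return by_read


def classify_segment_pair(
    a: AlignmentSegment, b: AlignmentSegment, min_delta: int = DEFAULT_MIN_SIG_LEN
) -> list[SignatureFragment]:
    """Classify one read-adjacent segment pair into signature fragments.

    Precedence: different chromosomes yield nothing here (translocation
    evidence is handled separately); discordant orientation marks both
    segments as inversion evidence; reference overlap marks both as tandem
    duplication evidence; otherwise the reference-gap/read-gap imbalance
    beyond ``min_delta`` yields one DEL or INS fragment.
    """
    if a.chrom != b.chrom:
        return []
    if a.is_reverse != b.is_reverse:
        return [
            SignatureFragment(a.read_id, a.chrom, a.ref_start, a.ref_end, "INV_SEG", "split", True),
            SignatureFragment(b.read_id, b.chrom, b.ref_start, b.ref_end, "INV_SEG", "split", True),
        ]
    # same orientation: order on the reference axis for gap arithmetic
    lo, hi = (a, b) if a.ref_start <= b.ref_start else (b, a)
    overlap = lo.ref_end - hi.ref_start
    if overlap > 0:
        return [
            SignatureFragment(lo.read_id, lo.chrom, lo.ref_start, lo.ref_end, "DUP_SEG", "split"),
            SignatureFragment(hi.read_id, hi.chrom, hi.ref_start, hi.ref_end, "DUP_SEG", "split"),
        ]
    ref_gap = hi.ref_start - lo.ref_end
    read_gap = b.read_start - a.read_end
    if ref_gap - read_gap > min_delta:
        return [
            SignatureFragment(lo.read_id, lo.chrom, lo.ref_end, hi.ref_start, "DEL", "split")
        ]
    if read_gap - ref_gap > min_delta:
        ins_len = read_gap - ref_gap
        anchor = lo.ref_end
        return [
            SignatureFragment(lo.read_id, lo.chrom, anchor, anchor + ins_len, "INS", "split")
        ]
    return []


def extract_split_fragments(
    segments_by_read: Mapping[str, list[AlignmentSegment]],
    min_delta: int = DEFAULT_MIN_SIG_LEN,
) -> list[SignatureFragment]:
    """Run :func:`classify_segment_pair` over every adjacent same-read pair."""
    fragments: list[SignatureFragment] = []
    for read_id in sorted(segments_by_read):
        segs = sorted(segments_by_read[read_id], key=lambda s: s.read_start)
        for a, b in zip(segs, segs[1:]):
            fragments.extend(classify_segment_pair(a, b, min_delta))
    fragments.sort(key=_fragment_sort_key)
    return fragments


def extract_tra_evidence(
    segments_by_read: Mapping[str, list[AlignmentSegment]]
) -> list[TraEvidence]:
    """Cross-chromosome adjacent segment pairs as canonical breakpoint records."""
    out: list[TraEvidence] = []
    for read_id in sorted(segments_by_read):
        segs = sorted(segments_by_read[read_id], key=lambda s: s.read_start)
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom:
                continue
            p1 = a.ref_start if a.is_reverse else a.ref_end
            p2 = b.ref_end if b.is_reverse else b.ref_start
            c1, c2 = a.chrom, b.chrom
            if (c2, p2) < (c1, p1):
                c1, p1, c2, p2 = c2, p2, c1, p1
            out.append(TraEvidence(read_id, c1, p1, c2, p2))
    out.sort(key=lambda t: (t.chrom1, t.pos1, t.chrom2, t.pos2, t.read_id))
    return out


def region_depth(
    bam: pysam.AlignmentFile, chrom: str, start: int, end: int
) -> RegionCoverage:
    """Mean depth over the region from primary, non-duplicate alignments.

    depth = (sum of per-read overlap lengths) / region length, rounded to two
    decimals.
    """
    if end - start < 1:
        raise ValueError(f"zero-length region {chrom}:{start}-{end}")
    total = 0
    for aln in bam.fetch(chrom, start, end):
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
            continue
        total += min(aln.reference_end, end) - max(aln.reference_start, start)
    return RegionCoverage(chrom, start, end, round(total / (end - start), 2))
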