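"""Encode alignment signatures around one candidate SV into a fixed-size RGB image.

The encoding follows per-type rules. A search region is derived from the
candidate's breakpoints and length ``svl``:

* DEL/DUP: ``[bpt_left - svl, bpt_right + svl]``
* INS:     ``[pos - svl, pos + 2*svl]``
* INV with ``svl <= alpha``: ``[bpt_left - svl, bpt_right + svl]``; longer
  inversions search only around the breakpoints, windows
  ``[bpt_left - alpha, bpt_left + alpha/2]`` and
  ``[bpt_right + alpha/2, bpt_right + alpha]``.

Each signature fragment found inside the region receives binary RGB channels:

* INS/DEL/DUP — B=255 iff the fragment lies completely inside the region;
  G=255 iff its midpoint falls between the breakpoints; R=255 iff its length
  is strictly less than ``2*svl``.
* INV — B=255 iff the evidence comes from a split read; G as above; R=255 iff
  the segment's orientation is discordant with its read mates.

Fragments are stacked into rows of a working canvas whose height tracks the
local read depth, then the canvas is resampled (nearest neighbour, which
preserves the binary channel values) to the configured image size so that
every candidate — of any length, at any coverage — yields the same-shaped
input for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from . import io_align
from .callset import SVRecord

DEFAULT_ALPHA = 10_000
DEFAULT_IMAGE_SIZE = 128


@dataclass(frozen=True)
class EncoderConfig:
    alpha: int = DEFAULT_ALPHA
    image_width: int = DEFAULT_IMAGE_SIZE
    image_height: int = DEFAULT_IMAGE_SIZE
    min_sig_len: int = io_align.DEFAULT_MIN_SIG_LEN
    min_mapq: int = io_align.DEFAULT_MIN_MAPQ
    max_stack_depth_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.image_width < 32 or self.image_height < 32:
            raise ValueError("image dimensions must be >= 32")


@dataclass(frozen=True)
class SearchRegion:
    """One or two disjoint, ordered genomic windows on one chromosome."""

    chrom: str
    windows: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for s, e in self.windows:
            if e <= s:
                raise ValueError(f"empty window {s}..{e}")
        for (s1, e1), (s2, e2) in zip(self.windows, self.windows[1:]):
            if s2 < e1:
                raise ValueError("windows must be disjoint and ordered")

    @property
    def span(self) -> int:
        return sum(e - s for s, e in self.windows)

    @property
    def start(self) -> int:
        return self.windows[0][0]

    @property
    def end(self) -> int:
        return self.windows[-1][1]

    def contains(self, start: int, end: int) -> bool:
        return any(start >= s and end <= e for s, e in self.windows)

    def overlaps(self, start: int, end: int) -> bool:
        return any(start < e and end > s for s, e in self.windows)


@dataclass
class EncodedImage:
    pixels: np.ndarray  # (H, W, 3) uint8
    candidate_id: str = "."
    svtype: str = "."
    region: SearchRegion | None = None
    depth: float = 0.0

    def to_png(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray(self.pixels, mode="RGB").save(str(path))

    @property
    def nonzero_row_fraction(self) -> float:
        rows = self.pixels.reshape(self.pixels.shape[0], -1).any(axis=1)
        return float(rows.mean())


class UnsupportedTypeError(ValueError):
    pass


def compute_search_region(
    record: SVRecord, config: EncoderConfig, contig_length: int | None = None
) -> SearchRegion:
    """Breakpoint-and-length derived search window(s), clipped to the contig."""
    svl = record.svlen
    left, right = record.bpt_left, record.bpt_right
    if record.svtype in ("DEL", "DUP"):
        windows = [(left - svl, right + svl)]
    elif record.svtype == "INS":
        windows = [(left - svl, left + 2 * svl)]
    elif record.svtype == "INV":
        if svl <= config.alpha:
            windows = [(left - svl, right + svl)]
        else:
            a = config.alpha
            windows = [(left - a, left + a // 2), (right + a // 2, right + a)]
    else:
        raise UnsupportedTypeError(f"cannot encode svtype {record.svtype}")
    clipped = []
    for s, e in windows:
        s = max(0, s)
        if contig_length is not None:
            e = min(e, contig_length)
        if e > s:
            clipped.append((s, e))
    if not clipped:
        raise ValueError(f"search region empty for {record.id}")
    return SearchRegion(record.chrom, tuple(clipped))


def assign_channels(
    fragment: io_align.SignatureFragment, region: SearchRegion, record: SVRecord
) -> tuple[int, int, int]:
    """Binary (R, G, B) values for one fragment under the per-type rules.

    Containment and length predicates use the fragment's true (unclipped)
    extent even when only part of it falls inside the region.
    """
    mid = (fragment.start + fragment.end) / 2
    g = 255 if record.bpt_left <= mid <= record.bpt_right else 0
    if record.svtype == "INV":
        b = 255 if fragment.source == "split" else 0
        r = 255 if fragment.orientation_discordant else 0
    else:
        b = 255 if region.contains(fragment.start, fragment.end) else 0
        r = 255 if fragment.length < 2 * record.svlen else 0
    return (r, g, b)


def _window_columns(region: SearchRegion) -> list[tuple[int, int, int]]:
    """Per-window (genome_start, genome_end, canvas column offset); 1 bp = 1 column,
    with a single black separator column between windows."""
    cols = []
    offset = 0
    for i, (s, e) in enumerate(region.windows):
        if i > 0:
            offset += 1  # separator
        cols.append((s, e, offset))
        offset += e - s
    return cols


def canvas_width(region: SearchRegion) -> int:
    return region.span + (len(region.windows) - 1)


def stack_and_rasterize(
    fragments: list[tuple[io_align.SignatureFragment, tuple[int, int, int]]],
    region: SearchRegion,
    depth: float,
    config: EncoderConfig,
) -> np.ndarray:
    """Pack channel-assigned fragments into depth-derived rows and resample.

    Fragments (sorted by start/end/read id) take the first row where their
    column span is still free; when every row is occupied the fragment is
    dropped. The working canvas is then resampled to the configured size with
    nearest-neighbour indexing, preserving the binary channel values.
    """
    rows = max(1, round(depth * config.max_stack_depth_factor))
    width = canvas_width(region)
    canvas = np.zeros((rows, width, 3), dtype=np.uint8)
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(rows)]
    cols = _window_columns(region)
    ordered = sorted(fragments, key=lambda fc: (fc[0].start, fc[0].end, fc[0].read_id))
    for frag, (r, g, b) in ordered:
        if r == 0 and g == 0 and b == 0:
            continue  # no rule fired: nothing to draw, keep the row free
        spans = []
        for gs, ge, off in cols:
            s = max(frag.start, gs)
            e = min(frag.end, ge)
            if e > s:
                spans.append((off + s - gs, off + e - gs))
        if not spans:
            continue
        for k in range(rows):
            if all(ce <= s or cs >= e for s, e in spans for cs, ce in occupied[k]):
                for s, e in spans:
                    canvas[k, s:e] = (r, g, b)
                    occupied[k].append((s, e))
                break
    h, w = config.image_height, config.image_width
    row_idx = (np.arange(h) * rows) // h
    col_idx = (np.arange(w) * width) // w
    return canvas[row_idx][:, col_idx]


def fragments_for_record(
    bam: pysam.AlignmentFile, record: SVRecord, region: SearchRegion, config: EncoderConfig
) -> list[io_align.SignatureFragment]:
    """Collect the signature fragments relevant to this record type inside the region.

    INS/DEL use intra-alignment (CIGAR) fragments plus same-type split-read
    fragments; INV and DUP use split-read segment evidence only.
    """
    frags: list[io_align.SignatureFragment] = []
    for s, e in region.windows:
        if record.svtype in ("INS", "DEL"):
            frags.extend(
                f
                for f in io_align.extract_cigar_fragments(
                    bam, region.chrom, s, e, config.min_sig_len, config.min_mapq
                )
                if f.sig_type == record.svtype
            )
    segs = {}
    for s, e in region.windows:
        for rid, rsegs in io_align.collect_segments(
            bam, region.chrom, s, e, config.min_mapq
        ).items():
            segs.setdefault(rid, []).extend(rsegs)
    for rsegs in segs.values():
        rsegs.sort(key=lambda x: x.read_start)
    dedup = {rid: sorted(set(v), key=lambda x: x.read_start) for rid, v in segs.items()}
    want = {"INS": ("INS",), "DEL": ("DEL",), "INV": ("INV_SEG",), "DUP": ("DUP_SEG",)}[
        record.svtype
    ]
    for f in io_align.extract_split_fragments(dedup, config.min_sig_len):
        if f.sig_type in want and region.overlaps(f.start, f.end):
            frags.append(f)
    # drop exact duplicates from overlapping window fetches
    seen = set()
    unique = []
    for f in sorted(frags, key=lambda f: (f.start, f.end, f.read_id, f.source)):
        key = (f.read_id, f.start, f.end, f.sig_type, f.source)
        if key not in seen:
            seen.add(key)
            unique.append(f)
    return unique


def encode_candidate(
    bam: pysam.AlignmentFile, record: SVRecord, config: EncoderConfig
) -> EncodedImage:
    """Full per-candidate encoding: region → fragments → channels → raster."""
    try:
        contig_len = bam.get_reference_length(record.chrom)
    except KeyError:
        contig_len = None
    region = compute_search_region(record, config, contig_len)
    depth_total = 0.0
    for s, e in region.windows:
        depth_total += io_align.region_depth(bam, region.chrom, s, e).depth * (e - s)
    depth = round(depth_total / region.span, 2)
    frags = fragments_for_record(bam, record, region, config)
    assigned = [(f, assign_channels(f, region, record)) for f in frags]
    pixels = stack_and_rasterize(assigned, region, depth, config)
    return EncodedImage(pixels, record.id, record.svtype, region, depth)
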