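"""Synthetic long-read alignment and callset generator.

Rather than running a read simulator plus an aligner, alignment records are
synthesized directly on a reference coordinate space: reads tile each contig
at the target coverage, and a read overlapping an embedded event carries the
alignment signature that a long-read aligner would produce for it —

* DEL/INS: a ``D``/``I`` CIGAR operation of (jittered) event length inside a
  single alignment;
* INV: the read is split into forward and reverse-complement segments at the
  inversion boundaries (primary + supplementary records with soft clips);
* DUP: a read crossing the tandem-copy junction is split into two overlapping
  forward segments;
* TRA: split pairs whose two segments map to different chromosomes.

Alongside the alignments, a truth VCF of the embedded events and a decoy VCF
of deliberately false candidates (signature-free loci, plus coordinate-shifted
copies of real events) are written, so labeling, encoding, training and
evaluation can all run without external data.

All randomness flows from ``SimConfig.seed``; the same config reproduces the
same files byte-for-byte (BAM payload included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .callset import DEFAULT_REFDIST, SVRecord, TraCluster, TraRecord, write_vcf

DEFAULT_CONTIGS = {"chr1": 3_000_000, "chr2": 1_500_000}
DEFAULT_EVENT_COUNTS = {"DEL": 30, "INS": 30, "INV": 15, "DUP": 15, "TRA": 4}
DEFAULT_LENGTH_RANGES = {
    "DEL": (60, 600),
    "INS": (60, 600),
    "INV": (600, 4000),
    "DUP": (1000, 5000),
}


@dataclass
class SimConfig:
    seed: int
    contigs: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CONTIGS))
    coverage: float = 30.0
    read_length_mean: int = 12_000
    read_length_sd: int = 1_500
    event_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_EVENT_COUNTS))
    length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_RANGES)
    )
    decoy_counts: dict[str, int] = field(
        default_factory=lambda: {"DEL": 15, "INS": 15, "INV": 15, "DUP": 15}
    )
    jitter_sd: float = 8.0
    small_indel_rate: float = 2e-5  # per-bp rate of sub-threshold noise indels
    decoy_shift: int = 5_000
    het_fraction: float = 1.0  # fraction of overlapping reads carrying the signature
    min_flank: int = 150  # bp a read must extend past an event to show its signature
    event_gap: int = 3_000

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for t, (lo, hi) in self.length_ranges.items():
            if lo < 50:
                raise ValueError(f"{t} minimum length {lo} < 50")


@dataclass(frozen=True)
class Event:
    id: str
    svtype: str
    chrom: str
    start: int  # 0-based
    length: int

    @property
    def end(self) -> int:
        return self.start if self.svtype == "INS" else self.start + self.length

    def to_record(self) -> SVRecord:
        return SVRecord(
            chrom=self.chrom,
            pos=self.start + 1,
            end=self.start + 1 if self.svtype == "INS" else self.end,
            svlen=self.length,
            svtype=self.svtype,
            id=self.id,
        )


@dataclass
class SimulatedDataset:
    bam_path: Path
    truth_vcf: Path
    decoy_vcf: Path
    events: list[Event]
    tra_truth: list[TraRecord]
    decoys: list[SVRecord]
    config: SimConfig


def _place_events(config: SimConfig, rng: np.random.Generator) -> tuple[list[Event], list[TraRecord]]:
    """Lay events left-to-right across contigs with reserved search-region space."""
    order: list[str] = []
    for svtype in ("DEL", "INS", "INV", "DUP"):
        order.extend([svtype] * config.event_counts.get(svtype, 0))
    rng.shuffle(order)
    contig_names = sorted(config.contigs)
    margin = config.read_length_mean
    cursors = {c: margin for c in contig_names}
    events: list[Event] = []
    counters = {t: 0 for t in ("DEL", "INS", "INV", "DUP")}
    ci = 0
    for svtype in order:
        lo, hi = config.length_ranges[svtype]
        length = int(rng.integers(lo, hi + 1))
        reserved = 3 * length + config.event_gap
        placed = False
        for _ in range(len(contig_names)):
            chrom = contig_names[ci % len(contig_names)]
            limit = config.contigs[chrom] - margin
            if cursors[chrom] + reserved < limit:
                start = cursors[chrom] + config.event_gap // 2 + length
                counters[svtype] += 1
                events.append(Event(f"{svtype}_{counters[svtype]:05d}", svtype, chrom, start, length))
                cursors[chrom] += reserved
                ci += 1
                placed = True
                break
            ci += 1
        if not placed:
            raise ValueError(
                f"cannot fit {svtype} event of {length} bp: contigs exhausted "
                f"(increase contig lengths or reduce event counts)"
            )
    tras: list[TraRecord] = []
    n_tra = config.event_counts.get("TRA", 0)
    if n_tra and len(contig_names) < 2:
        raise ValueError("TRA events need at least two contigs")
    for i in range(n_tra):
        c1, c2 = contig_names[0], contig_names[1]
        lim1 = config.contigs[c1] - margin
        lim2 = config.contigs[c2] - margin
        if cursors[c1] + 2 * config.event_gap >= lim1 or cursors[c2] + 2 * config.event_gap >= lim2:
            raise ValueError("cannot fit TRA breakpoints: contigs exhausted")
        p1 = cursors[c1] + config.event_gap
        p2 = cursors[c2] + config.event_gap
        cursors[c1] += 2 * config.event_gap
        cursors[c2] += 2 * config.event_gap
        tras.append(TraRecord.canonical(c1, p1 + 1, c2, p2 + 1, caller="truth", id=f"TRA_{i + 1:05d}"))
    return events, tras


def _jitter(length: int, rng: np.random.Generator, sd: float) -> int:
    return max(1, int(round(length + rng.normal(0, sd))))


@dataclass
class _Seg:
    """One alignment record awaiting serialization."""

    qname: str
    chrom: str
    ref_start: int
    cigar: list[tuple[int, int]]
    is_reverse: bool
    is_supplementary: bool


def _noise_ops(span: int, rng: np.random.Generator, rate: float) -> list[tuple[int, int]]:
    """Split a match stretch with occasional sub-threshold indels."""
    ops: list[tuple[int, int]] = []
    remaining = span
    while remaining > 0:
        if rate > 0:
            nxt = int(rng.geometric(min(1.0, rate)))
        else:
            nxt = remaining + 1
        if nxt >= remaining or remaining < 100:
            ops.append((0, remaining))
            break
        ops.append((0, nxt))
        remaining -= nxt
        ilen = int(rng.integers(1, 40))
        if rng.random() < 0.5:
            ops.append((1, ilen))  # small insertion: no reference consumed
        else:
            ilen = min(ilen, remaining - 50)
            if ilen >= 1:
                ops.append((2, ilen))
                remaining -= ilen
    return ops


def _reads_for_contig(
    chrom: str,
    contig_len: int,
    events: list[Event],
    config: SimConfig,
    rng: np.random.Generator,
    name_prefix: str,
) -> list[_Seg]:
    n_reads = int(np.ceil(config.coverage * contig_len / config.read_length_mean))
    ev = sorted((e for e in events if e.chrom == chrom), key=lambda e: e.start)
    segs: list[_Seg] = []
    for i in range(n_reads):
        rlen = int(np.clip(rng.normal(config.read_length_mean, config.read_length_sd), 1000, None))
        s = int(rng.integers(0, max(1, contig_len - 1000)))
        e = min(s + rlen, contig_len)
        if e - s < 1000:
            continue
        qname = f"{name_prefix}_{i:07d}"
        carrier = rng.random() < config.het_fraction
        segs.extend(_build_read(qname, chrom, s, e, ev, carrier, config, rng))
    return segs


def _build_read(
    qname: str,
    chrom: str,
    s: int,
    e: int,
    events: list[Event],
    carrier: bool,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[_Seg]:
    """Synthesize the alignment record(s) of one read over [s, e)."""
    flank = config.min_flank
    spanned = [
        ev
        for ev in events
        if carrier and ev.start - s >= flank and e - max(ev.end, ev.start + 1) >= flank
    ]
    split_ev = next((ev for ev in spanned if ev.svtype in ("INV", "DUP")), None)
    if split_ev is not None and split_ev.svtype == "INV":
        return _inv_read(qname, chrom, s, e, split_ev, rng, config)
    if split_ev is not None and split_ev.svtype == "DUP":
        return _dup_read(qname, chrom, s, e, split_ev, rng, config)
    # clip the read so it does not cross INV/DUP boundaries it cannot represent
    for ev in events:
        if ev.svtype in ("INV", "DUP") and ev not in spanned:
            if s < ev.start < e:
                e = ev.start
            elif s < ev.end < e:
                s = ev.end
    if e - s < 500:
        return []
    cigar: list[tuple[int, int]] = []
    pos = s
    for ev in sorted(spanned, key=lambda x: x.start):
        if ev.svtype not in ("DEL", "INS") or ev.start < pos:
            continue
        cigar.extend(_noise_ops(ev.start - pos, rng, config.small_indel_rate))
        jlen = _jitter(ev.length, rng, config.jitter_sd)
        if ev.svtype == "DEL":
            cigar.append((2, ev.end - ev.start))
            pos = ev.end
        else:
            cigar.append((1, jlen))
            pos = ev.start
    if e - pos > 0:
        cigar.extend(_noise_ops(e - pos, rng, config.small_indel_rate))
    return [_Seg(qname, chrom, s, _merge_cigar(cigar), False, False)]


def _merge_cigar(ops: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def _clipped(cigar, left, right):
    ops = []
    if left > 0:
        ops.append((4, left))
    ops.extend(cigar)
    if right > 0:
        ops.append((4, right))
    return ops


def _inv_read(qname, chrom, s, e, ev, rng, config) -> list[_Seg]:
    """Forward / reversed / forward segments around an inversion."""
    total = e - s
    pieces = []  # (ref_start, ref_end, reverse, read_start)
    roff = 0
    if ev.start > s:
        pieces.append((s, ev.start, False, roff))
        roff += ev.start - s
    pieces.append((ev.start, ev.end, True, roff))
    roff += ev.end - ev.start
    if e > ev.end:
        pieces.append((ev.end, e, False, roff))
        roff += e - ev.end
    # the aligner would report the longest piece as the primary alignment
    primary = max(range(len(pieces)), key=lambda k: pieces[k][1] - pieces[k][0])
    segs = []
    for k, (rs, re, rev, off) in enumerate(pieces):
        span = re - rs
        if rev:
            left, right = total - (off + span), off
        else:
            left, right = off, total - (off + span)
        segs.append(_Seg(qname, chrom, rs, _clipped([(0, span)], left, right), rev, k != primary))
    return segs


def _dup_read(qname, chrom, s, e, ev, rng, config) -> list[_Seg]:
    """Two overlapping forward segments for a read crossing the tandem junction."""
    total = e - s
    a_span = ev.end - s  # [s, ev.end)
    b_ref_start = ev.start
    b_span = total - a_span
    b_span = min(b_span, (ev.end - ev.start) + (e - ev.end))
    if b_span < 100:
        return [_Seg(qname, chrom, s, [(0, total)], False, False)]
    a_primary = a_span >= b_span
    segs = [
        _Seg(qname, chrom, s, _clipped([(0, a_span)], 0, total - a_span), False, not a_primary),
        _Seg(qname, chrom, b_ref_start, _clipped([(0, b_span)], a_span, total - a_span - b_span), False, a_primary),
    ]
    return segs


def _tra_reads(
    tras: list[TraRecord], config: SimConfig, rng: np.random.Generator
) -> list[_Seg]:
    segs: list[_Seg] = []
    n_reads = max(5, int(round(config.coverage / 3)))
    for t_i, tra in enumerate(tras):
        for j in range(n_reads):
            half = int(np.clip(rng.normal(config.read_length_mean / 2, config.read_length_sd), 1000, None))
            p1, p2 = tra.pos1 - 1, tra.pos2 - 1
            half = min(half, p1 - 1, config.contigs[tra.chrom2] - p2 - 1)
            if half < 500:
                continue
            total = 2 * half
            qname = f"tra_{t_i:03d}_{j:04d}"
            segs.append(
                _Seg(qname, tra.chrom1, p1 - half, _clipped([(0, half)], 0, half), False, False)
            )
            segs.append(
                _Seg(qname, tra.chrom2, p2, _clipped([(0, half)], half, 0), False, True)
            )
    return segs


def _make_decoys(
    events: list[Event], config: SimConfig, rng: np.random.Generator
) -> list[SVRecord]:
    """False candidates: half at signature-free loci, half shifted off real events."""
    contig_names = sorted(config.contigs)
    # a decoy only picks up misleading signal from same-type signatures, since
    # the encoder selects fragments by signature type; avoidance is per type
    busy: dict[tuple[str, str], list[tuple[int, int]]] = {
        (t, c): [] for t in ("DEL", "INS", "INV", "DUP") for c in contig_names
    }
    for ev in events:
        pad = 3 * ev.length + 2000
        if ev.svtype in ("INV", "DUP"):
            # split segments of spanning reads extend a read length past the event
            pad += config.read_length_mean
        busy[(ev.svtype, ev.chrom)].append((ev.start - pad, max(ev.end, ev.start + 1) + pad))
    decoys: list[SVRecord] = []
    for svtype in sorted(config.decoy_counts):
        n = config.decoy_counts[svtype]
        lo, hi = config.length_ranges[svtype]
        same_type = [e for e in events if e.svtype == svtype]
        for k in range(n):
            length = int(rng.integers(lo, hi + 1))
            if k % 2 == 0 or not same_type:
                # random signature-free locus
                for _ in range(200):
                    chrom = contig_names[int(rng.integers(len(contig_names)))]
                    margin = config.read_length_mean
                    start = int(rng.integers(margin, config.contigs[chrom] - margin - 3 * length))
                    span = (start - 2 * length, start + 3 * length)
                    if all(
                        span[1] <= b0 or span[0] >= b1 for b0, b1 in busy[(svtype, chrom)]
                    ):
                        busy[(svtype, chrom)].append(span)
                        break
                else:
                    warnings.warn(f"could not place signature-free {svtype} decoy; skipped")
                    continue
            else:
                src = same_type[int(rng.integers(len(same_type)))]
                chrom = src.chrom
                src_pad = 3 * src.length + 2000
                if svtype in ("INV", "DUP"):
                    src_pad += config.read_length_mean
                start = None
                margin = config.read_length_mean
                usable = config.contigs[chrom] - 2 * margin - 3 * length
                base_shift = max(config.decoy_shift, src_pad + 3 * length)
                for _ in range(200):
                    # displaced far enough to clear both the labeling radius and
                    # the source event's (long) split segments; wraps around the
                    # contig so dense event regions can be escaped
                    shift = base_shift + int(rng.integers(0, max(1, usable)))
                    cand = margin + (src.start - margin + shift) % usable
                    span = (cand - 2 * length, cand + 3 * length)
                    if all(
                        abs(cand - e2.start) > 2 * DEFAULT_REFDIST
                        for e2 in same_type
                        if e2.chrom == chrom
                    ) and all(
                        span[1] <= b0 or span[0] >= b1 for b0, b1 in busy[(svtype, chrom)]
                    ):
                        busy[(svtype, chrom)].append(span)
                        start = cand
                        break
                if start is None:
                    warnings.warn(f"could not place shifted {svtype} decoy; skipped")
                    continue
            decoys.append(
                SVRecord(
                    chrom=chrom,
                    pos=start + 1,
                    end=start + 1 if svtype == "INS" else start + length,
                    svlen=length,
                    svtype=svtype,
                    id=f"decoy_{svtype}_{k + 1:05d}",
                )
            )
    return decoys


def simulate_dataset(config: SimConfig, outdir: str | Path) -> SimulatedDataset:
    """Generate the BAM (+index), truth VCF and decoy VCF for one configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    events, tras = _place_events(config, rng)
    segs: list[_Seg] = []
    for chrom in sorted(config.contigs):
        segs.extend(
            _reads_for_contig(chrom, config.contigs[chrom], events, config, rng, f"read_{chrom}")
        )
    segs.extend(_tra_reads(tras, config, rng))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": config.contigs[c]} for c in sorted(config.contigs)],
    }
    tid = {c: i for i, c in enumerate(sorted(config.contigs))}
    segs.sort(key=lambda s: (tid[s.chrom], s.ref_start, s.qname, s.is_supplementary))
    bam_path = outdir / "alignments.bam"
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for seg in segs:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = seg.qname
            a.reference_id = tid[seg.chrom]
            a.reference_start = seg.ref_start
            a.mapping_quality = 60
            a.cigartuples = seg.cigar
            a.flag = (0x10 if seg.is_reverse else 0) | (0x800 if seg.is_supplementary else 0)
            bam.write(a)
    pysam.index(str(bam_path))

    truth_vcf = outdir / "truth.vcf"
    decoy_vcf = outdir / "decoys.vcf"
    truth_records = [ev.to_record() for ev in events]
    write_vcf(truth_records, [TraCluster([t]) for t in tras], truth_vcf, config.contigs)
    decoys = _make_decoys(events, config, rng)
    write_vcf(decoys, [], decoy_vcf, config.contigs)
    return SimulatedDataset(bam_path, truth_vcf, decoy_vcf, events, tras, decoys, config)


def make_training_fixture(
    dataset: SimulatedDataset,
    encoder_config,
    mislabel_fraction: float = 0.0,
    seed: int | None = None,
):
    """Encode truth events (positives) and decoys (negatives) into a labeled set.

    Optionally relabels a fraction of the positives as negatives ("planted"
    mislabels) to exercise mislabel recovery. Returns (images, manifest) where
    manifest rows are dicts with id, svtype, label, planted.
    """
    from . import encoder as enc

    rng = np.random.default_rng(dataset.config.seed if seed is None else seed)
    entries: list[tuple[SVRecord, str, bool]] = []
    pos_records = [ev.to_record() for ev in dataset.events]
    n_plant = int(round(mislabel_fraction * len(pos_records)))
    plant_idx = set(rng.choice(len(pos_records), size=n_plant, replace=False).tolist()) if n_plant else set()
    for i, rec in enumerate(pos_records):
        if i in plant_idx:
            entries.append((rec, "negative", True))
        else:
            entries.append((rec, "positive", False))
    for rec in dataset.decoys:
        entries.append((rec, "negative", False))
    images = []
    manifest = []
    with pysam.AlignmentFile(str(dataset.bam_path)) as bam:
        for rec, label, planted in entries:
            img = enc.encode_candidate(bam, rec, encoder_config)
            images.append(img)
            manifest.append(
                {"id": rec.id, "svtype": rec.svtype, "label": label, "planted": planted}
            )
    return images, manifest
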