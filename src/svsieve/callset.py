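"""Multi-caller SV callset handling: VCF I/O, merging, labeling, TRA clustering.

Records are carried as :class:`SVRecord` (VCF-style 1-based ``pos``/``end``;
``start0``/``end0`` expose the 0-based half-open view used internally).
Translocations are breakpoint-level records (:class:`TraRecord`) and are never
imaged; they are merged by a distance predicate and kept when enough distinct
callers agree.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

SV_TYPES = ("INS", "DEL", "INV", "DUP")
DEFAULT_MIN_SVLEN = 50
DEFAULT_GAMMA = 1000
DEFAULT_C0 = 2
DEFAULT_REFDIST = 1000
DEFAULT_PCTSIZE = 0.7


@dataclass
class SVRecord:
    """One candidate or truth variant.

    ``pos`` is the 1-based left breakpoint (insertion point for INS); ``end``
    the 1-based right breakpoint. For DEL/INV/DUP, ``svlen = end - pos`` is
    reconciled on load.
    """

    chrom: str
    pos: int
    end: int
    svlen: int
    svtype: str
    callers: frozenset[str] = frozenset()
    id: str = "."
    qual: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.svtype != "TRA" and self.end < self.pos:
            raise ValueError(f"end {self.end} < pos {self.pos} for {self.svtype}")
        if self.svlen < 0:
            raise ValueError("svlen must be >= 0")

    @property
    def start0(self) -> int:
        return self.pos - 1

    @property
    def end0(self) -> int:
        return self.end - 1 if self.svtype == "INS" else self.end

    @property
    def bpt_left(self) -> int:
        """0-based left breakpoint."""
        return self.start0

    @property
    def bpt_right(self) -> int:
        """0-based right breakpoint (synthetic ``pos + svlen`` span for INS)."""
        return self.start0 + self.svlen if self.svtype == "INS" else self.end0


@dataclass(frozen=True)
class TraRecord:
    """One translocation breakpoint pair, canonically ordered."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    caller: str = "unknown"
    id: str = "."

    @staticmethod
    def canonical(chrom1, pos1, chrom2, pos2, caller="unknown", id=".") -> "TraRecord":
        if (chrom2, pos2) < (chrom1, pos1):
            chrom1, pos1, chrom2, pos2 = chrom2, pos2, chrom1, pos1
        return TraRecord(chrom1, pos1, chrom2, pos2, caller, id)


@dataclass
class TraCluster:
    members: list[TraRecord]

    @property
    def support(self) -> int:
        return len({m.caller for m in self.members})

    @property
    def representative(self) -> TraRecord:
        return TraRecord(
            self.members[0].chrom1,
            int(statistics.median(m.pos1 for m in self.members)),
            self.members[0].chrom2,
            int(statistics.median(m.pos2 for m in self.members)),
            caller=",".join(sorted({m.caller for m in self.members})),
            id=self.members[0].id,
        )


@dataclass
class LabeledCandidate:
    record: SVRecord
    label: str  # positive | negative
    matched_truth_id: str = ""

    def __post_init__(self) -> None:
        if (self.label == "positive") != bool(self.matched_truth_id):
            raise ValueError("positive label iff matched_truth_id set")


class VcfParseError(ValueError):
    pass


def _infer_svtype(rec: pysam.VariantRecord) -> str | None:
    svtype = rec.info.get("SVTYPE")
    if svtype is None and rec.alts:
        alt = rec.alts[0]
        if alt.startswith("<") and alt.endswith(">"):
            svtype = alt.strip("<>").split(":")[0]
        elif "[" in alt or "]" in alt:
            svtype = "BND"
    if isinstance(svtype, (tuple, list)):
        svtype = svtype[0]
    return svtype


def _parse_bnd_mate(alt: str) -> tuple[str, int]:
    # e.g. N[chr5:2000[  or  ]chr5:2000]N
    for br in ("[", "]"):
        if br in alt:
            inner = alt.split(br)[1]
            chrom, pos = inner.split(":")
            return chrom, int(pos)
    raise VcfParseError(f"cannot parse BND ALT {alt!r}")


def load_vcf(
    path: str | Path,
    min_svlen: int = DEFAULT_MIN_SVLEN,
    caller: str | None = None,
) -> tuple[list[SVRecord], list[TraRecord]]:
    """Load one caller's VCF into SV records and TRA breakpoint records.

    Records with |SVLEN| below ``min_svlen`` are dropped (TRA exempt);
    DEL/INV/DUP lengths are reconciled to ``end - pos``.
    """
    records: list[SVRecord] = []
    tras: list[TraRecord] = []
    caller_name = caller or Path(path).stem
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf.fetch() if vf.index is not None else vf):
            try:
                svtype = _infer_svtype(rec)
                if svtype is None:
                    continue
                if svtype in ("TRA", "BND"):
                    chr2 = rec.info.get("CHR2")
                    if chr2 is not None:
                        # mate position in INFO/POS2, or INFO/END (pysam: rec.stop)
                        # for callers that abuse END across chromosomes
                        pos2 = rec.info.get("POS2")
                        if isinstance(pos2, (tuple, list)):
                            pos2 = pos2[0]
                        if pos2 is None:
                            pos2 = rec.stop
                        tras.append(
                            TraRecord.canonical(rec.chrom, rec.pos, str(chr2), int(pos2),
                                                caller_name, rec.id or ".")
                        )
                    elif rec.alts and ("[" in rec.alts[0] or "]" in rec.alts[0]):
                        mchrom, mpos = _parse_bnd_mate(rec.alts[0])
                        if mchrom == rec.chrom:
                            continue  # intra-chromosomal breakend: not a TRA
                        tras.append(
                            TraRecord.canonical(rec.chrom, rec.pos, mchrom, mpos,
                                                caller_name, rec.id or ".")
                        )
                    continue
                if svtype not in SV_TYPES:
                    continue
                svlen = rec.info.get("SVLEN")
                if isinstance(svlen, (tuple, list)):
                    svlen = svlen[0]
                end = rec.stop  # pysam: INFO/END or pos + len(ref) - 1, 1-based
                if svtype == "INS":
                    if svlen is None:
                        raise VcfParseError("INS without SVLEN")
                    svlen = abs(int(svlen))
                    end = rec.pos
                else:
                    if end is not None and end > rec.pos:
                        svlen = end - rec.pos
                    elif svlen is not None:
                        svlen = abs(int(svlen))
                        end = rec.pos + svlen
                    else:
                        raise VcfParseError(f"{svtype} without END or SVLEN")
                if svlen < min_svlen:
                    continue
                records.append(
                    SVRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        end=int(end),
                        svlen=int(svlen),
                        svtype=svtype,
                        callers=frozenset({caller_name}),
                        id=rec.id or f"{caller_name}_{i}",
                        qual=rec.qual,
                    )
                )
            except VcfParseError:
                raise
            except Exception as exc:  # surface the offending record
                raise VcfParseError(f"{path}: record {i} ({rec.chrom}:{rec.pos}): {exc}") from exc
    records.sort(key=lambda r: (r.chrom, r.pos, r.svtype, r.id))
    return records, tras


def merge_callsets(
    callsets: Sequence[tuple[str, Sequence[SVRecord]]],
    merge_dist: int = DEFAULT_REFDIST,
    size_sim: float = DEFAULT_PCTSIZE,
) -> list[SVRecord]:
    """Collapse same-type records from several callers into a consensus set.

    Same-type records whose positions lie within ``merge_dist`` of a group
    representative and whose length ratio is at least ``size_sim`` are
    grouped; the surviving record takes member-wise median pos/end/svlen and
    the union of caller names. Greedy in sorted order, hence deterministic and
    idempotent.
    """
    if not callsets:
        raise ValueError("need at least one callset")
    pool: list[SVRecord] = []
    for name, recs in callsets:
        for r in recs:
            pool.append(replace(r, callers=r.callers | {name}))
    pool.sort(key=lambda r: (r.chrom, r.svtype, r.pos, r.svlen, r.id))
    groups: list[list[SVRecord]] = []
    for rec in pool:
        placed = False
        for grp in groups:
            head = grp[0]
            if head.chrom != rec.chrom or head.svtype != rec.svtype:
                continue
            ref_pos = int(statistics.median(g.pos for g in grp))
            ref_len = statistics.median(g.svlen for g in grp)
            lo, hi = sorted((ref_len, rec.svlen))
            if abs(rec.pos - ref_pos) <= merge_dist and (hi == 0 or lo / hi >= size_sim):
                grp.append(rec)
                placed = True
                break
        if not placed:
            groups.append([rec])
    merged: list[SVRecord] = []
    for grp in groups:
        pos = int(statistics.median(g.pos for g in grp))
        svlen = int(statistics.median(g.svlen for g in grp))
        svtype = grp[0].svtype
        end = pos if svtype == "INS" else pos + svlen
        callers = frozenset().union(*(g.callers for g in grp))
        quals = [g.qual for g in grp if g.qual is not None]
        merged.append(
            SVRecord(
                chrom=grp[0].chrom,
                pos=pos,
                end=end,
                svlen=svlen,
                svtype=svtype,
                callers=callers,
                id=grp[0].id,
                qual=max(quals) if quals else None,
            )
        )
    merged.sort(key=lambda r: (r.chrom, r.pos, r.svtype, r.id))
    return merged


def tra_same_event(a: TraRecord, b: TraRecord, gamma: int = DEFAULT_GAMMA) -> bool:
    """True iff both chromosome pairs match and both breakpoint offsets are within gamma."""
    return (
        a.chrom1 == b.chrom1
        and a.chrom2 == b.chrom2
        and abs(a.pos1 - b.pos1) <= gamma
        and abs(a.pos2 - b.pos2) <= gamma
    )


def merge_tras(
    records: Iterable[TraRecord],
    gamma: int = DEFAULT_GAMMA,
    c0: int = DEFAULT_C0,
) -> list[TraCluster]:
    """Greedy single-linkage clustering of TRA records; keep clusters with
    support from at least ``c0`` distinct callers.

    Records are processed in sorted order; each joins the first cluster whose
    current representative it matches under :func:`tra_same_event`, otherwise
    it founds a new cluster.
    """
    if c0 < 1:
        raise ValueError("c0 must be >= 1")
    clusters: list[TraCluster] = []
    for rec in sorted(records, key=lambda t: (t.chrom1, t.pos1, t.chrom2, t.pos2, t.caller)):
        for cl in clusters:
            if tra_same_event(rec, cl.representative, gamma):
                cl.members.append(rec)
                break
        else:
            clusters.append(TraCluster([rec]))
    return [cl for cl in clusters if cl.support >= c0]


def label_candidates(
    candidates: Sequence[SVRecord],
    truth: Sequence[SVRecord],
    refdist: int = DEFAULT_REFDIST,
    pctsize: float = DEFAULT_PCTSIZE,
) -> list[LabeledCandidate]:
    """One-to-one match candidates against a truth set.

    A candidate is positive iff a same-type truth record on the same
    chromosome lies within ``refdist`` and the length ratio
    ``min(len)/max(len)`` is at least ``pctsize``. Each truth record matches
    at most one candidate (the closest); all remaining candidates are
    negative.
    """
    pairs: list[tuple[int, int, int, int]] = []  # (distance, cand_idx, truth_idx)
    for ci, cand in enumerate(candidates):
        for ti, tr in enumerate(truth):
            if cand.svtype != tr.svtype or cand.chrom != tr.chrom:
                continue
            dist = abs(cand.pos - tr.pos)
            if dist > refdist:
                continue
            lo, hi = sorted((cand.svlen, tr.svlen))
            if hi > 0 and lo / hi < pctsize:
                continue
            pairs.append((dist, abs(cand.svlen - tr.svlen), ci, ti))
    pairs.sort()
    matched_c: dict[int, str] = {}
    used_t: set[int] = set()
    for _, _, ci, ti in pairs:
        if ci in matched_c or ti in used_t:
            continue
        matched_c[ci] = truth[ti].id
        used_t.add(ti)
    return [
        LabeledCandidate(c, "positive", matched_c[i])
        if i in matched_c
        else LabeledCandidate(c, "negative")
        for i, c in enumerate(candidates)
    ]


def write_vcf(
    records: Sequence[SVRecord],
    tra_clusters: Sequence[TraCluster],
    path: str | Path,
    contigs: dict[str, int],
    extra_header: Sequence[str] = (),
) -> None:
    """Write a sorted VCF 4.2 with SVTYPE/END/SVLEN/SUPPORT INFO keys."""
    header = pysam.VariantHeader()
    for line in extra_header:
        header.add_line(line)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_meta("INFO", items=[("ID", "SVTYPE"), ("Number", 1), ("Type", "String"),
                                   ("Description", "Type of structural variant")])
    header.add_meta("INFO", items=[("ID", "END"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "End position of the variant")])
    header.add_meta("INFO", items=[("ID", "SVLEN"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "Length of the variant")])
    header.add_meta("INFO", items=[("ID", "SUPPORT"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "Number of callers supporting the variant")])
    header.add_meta("INFO", items=[("ID", "CHR2"), ("Number", 1), ("Type", "String"),
                                   ("Description", "Mate chromosome for translocations")])
    header.add_meta("INFO", items=[("ID", "POS2"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "Mate position on CHR2 for translocations")])
    header.add_meta("FILTER", items=[("ID", "PASS"), ("Description", "All filters passed")])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        rows = []
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.id)):
            v = out.new_record(
                contig=r.chrom,
                start=r.start0,
                stop=r.pos if r.svtype == "INS" else r.end,
                alleles=("N", f"<{r.svtype}>"),
                id=r.id,
                qual=r.qual,
                filter="PASS",
            )
            v.info["SVTYPE"] = r.svtype
            v.info["SVLEN"] = r.svlen
            v.info["SUPPORT"] = len(r.callers) or 1
            rows.append(v)
        for cl in tra_clusters:
            rep = cl.representative
            v = out.new_record(
                contig=rep.chrom1,
                start=rep.pos1 - 1,
                stop=rep.pos1,
                alleles=("N", "<TRA>"),
                id=rep.id,
                filter="PASS",
            )
            v.info["SVTYPE"] = "TRA"
            v.info["CHR2"] = rep.chrom2
            v.info["POS2"] = rep.pos2
            v.info["SUPPORT"] = cl.support
            rows.append(v)
        rows.sort(key=lambda v: (v.chrom, v.pos))
        for v in rows:
            out.write(v)
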