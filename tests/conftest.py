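"""Shared fixtures: small synthetic datasets and BAM-building helpers."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from svsieve.simulate import SimConfig, SimulatedDataset, simulate_dataset


def make_bam(path: Path, contigs: dict[str, int], reads) -> Path:
    """Write and index a BAM from (qname, chrom, pos, cigar, flags, mapq) tuples."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": l} for c, l in contigs.items()],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    rows = []
    for qname, chrom, pos, cigar, flag, mapq in reads:
        a = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(header))
        a.query_name = qname
        a.reference_id = tid[chrom]
        a.reference_start = pos
        a.cigarstring = cigar
        a.flag = flag
        a.mapping_quality = mapq
        rows.append(a)
    rows.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for a in rows:
            bam.write(a)
    pysam.index(str(path))
    return path


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory) -> SimulatedDataset:
    """A compact 30x dataset exercising all event types."""
    config = SimConfig(
        seed=11,
        contigs={"chr1": 2_000_000, "chr2": 1_200_000},
        event_counts={"DEL": 8, "INS": 8, "INV": 4, "DUP": 4, "TRA": 2},
        decoy_counts={"DEL": 4, "INS": 4, "INV": 4, "DUP": 4},
    )
    return simulate_dataset(config, tmp_path_factory.mktemp("small_sim"))


@pytest.fixture(scope="session")
def small_bam(small_sim) -> pysam.AlignmentFile:
    with pysam.AlignmentFile(str(small_sim.bam_path)) as bam:
        yield bam
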