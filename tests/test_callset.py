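"""Callset handling: VCF round trips, merging, TRA clustering, labeling."""

from __future__ import annotations

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svsieve import callset as cs
from svsieve.callset import (
    SVRecord,
    TraRecord,
    label_candidates,
    load_vcf,
    merge_callsets,
    merge_tras,
    tra_same_event,
    write_vcf,
)


def _del(pos, svlen, chrom="chr1", id="x", callers=frozenset()):
    return SVRecord(chrom, pos, pos + svlen, svlen, "DEL", callers, id)


class TestLoadWrite:
    def test_del_svlen_reconciled_from_end(self, tmp_path):
        p = tmp_path / "d.vcf"
        recs = [SVRecord("chr1", 100, 200, 100, "DEL", id="d1")]
        write_vcf(recs, [], p, {"chr1": 10_000})
        loaded, _ = load_vcf(p)
        assert loaded[0].svlen == 100 and loaded[0].pos == 100 and loaded[0].end == 200

    def test_ins_has_point_position(self, tmp_path):
        p = tmp_path / "i.vcf"
        write_vcf([SVRecord("chr1", 500, 500, 300, "INS", id="i1")], [], p, {"chr1": 10_000})
        loaded, _ = load_vcf(p)
        assert loaded[0].svtype == "INS" and loaded[0].pos == loaded[0].end == 500
        assert loaded[0].svlen == 300

    def test_short_records_dropped_tra_exempt(self, tmp_path):
        p = tmp_path / "s.vcf"
        from svsieve.callset import TraCluster

        write_vcf(
            [_del(100, 30, id="short"), _del(1000, 80, id="long")],
            [TraCluster([TraRecord("chr1", 50, "chr2", 70, "a")])],
            p,
            {"chr1": 10_000, "chr2": 10_000},
        )
        recs, tras = load_vcf(p, min_svlen=50)
        assert [r.id for r in recs] == ["long"]
        assert len(tras) == 1 and tras[0].pos2 == 70

    def test_truth_vcf_round_trip_loss_free(self, small_sim):
        recs, tras = load_vcf(small_sim.truth_vcf, caller="truth")
        by_id = {r.id: r for r in recs}
        assert len(recs) == len(small_sim.events)
        for ev in small_sim.events:
            r = by_id[ev.id]
            assert (r.chrom, r.pos, r.svlen, r.svtype) == (
                ev.chrom, ev.start + 1, ev.length, ev.svtype,
            )
        assert [(t.chrom1, t.pos1, t.chrom2, t.pos2) for t in tras] == [
            (t.chrom1, t.pos1, t.chrom2, t.pos2) for t in small_sim.tra_truth
        ]

    def test_written_vcf_passes_external_validator(self, small_sim, tmp_path):
        out = subprocess.run(
            ["bcftools", "view", str(small_sim.truth_vcf)],
            capture_output=True, text=True,
        )
        assert out.returncode == 0, out.stderr
        assert "error" not in out.stderr.lower()

    def test_empty_input_header_only(self, tmp_path):
        p = tmp_path / "empty.vcf"
        write_vcf([], [], p, {"chr1": 1000})
        recs, tras = load_vcf(p)
        assert recs == [] and tras == []


class TestMergeCallsets:
    def test_nearby_same_type_collapse_with_caller_union(self):
        a = _del(1000, 100, id="a")
        b = _del(1010, 105, id="b")
        merged = merge_callsets([("A", [a]), ("B", [b])], merge_dist=1000, size_sim=0.7)
        assert len(merged) == 1
        assert merged[0].callers == {"A", "B"}
        assert merged[0].pos == 1005

    def test_type_mismatch_never_merges(self):
        d = _del(1000, 100, id="d")
        i = SVRecord("chr1", 1000, 1000, 100, "INS", id="i")
        merged = merge_callsets([("A", [d]), ("B", [i])])
        assert len(merged) == 2

    def test_perturbed_duplicates_from_four_callers_collapse_exactly(self, small_sim):
        rng = np.random.default_rng(17)
        truth = [ev.to_record() for ev in small_sim.events]
        callsets = []
        for name in ("c1", "c2", "c3", "c4"):
            recs = []
            for t in truth:
                shift = int(rng.integers(-100, 101))
                scale = 1 + rng.uniform(-0.05, 0.05)
                svlen = max(50, int(round(t.svlen * scale)))
                pos = max(1, t.pos + shift)
                end = pos if t.svtype == "INS" else pos + svlen
                recs.append(SVRecord(t.chrom, pos, end, svlen, t.svtype, id=f"{name}_{t.id}"))
            callsets.append((name, recs))
        merged = merge_callsets(callsets, merge_dist=1000, size_sim=0.7)
        assert len(merged) == len(truth)
        assert all(m.callers == {"c1", "c2", "c3", "c4"} for m in merged)

    def test_idempotent(self, small_sim):
        truth = [ev.to_record() for ev in small_sim.events]
        once = merge_callsets([("A", truth)])
        twice = merge_callsets([("merged", once)])
        assert [(m.chrom, m.pos, m.end, m.svlen, m.svtype) for m in once] == [
            (m.chrom, m.pos, m.end, m.svlen, m.svtype) for m in twice
        ]


# --- TRA ---------------------------------------------------------------------


def closure_oracle(records, gamma, c0):
    """Transitive-closure clustering over the pairwise predicate, then support filter."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if tra_same_event(records[i], records[j], gamma):
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(records[i])
    kept = [g for g in groups.values() if len({m.caller for m in g}) >= c0]
    return {frozenset((m.chrom1, m.pos1, m.chrom2, m.pos2, m.caller) for m in g) for g in kept}


def random_tra_records(rng, n_events=8, n_records=50, gamma=1000):
    """Noisy caller copies of well-separated true translocation events."""
    centers = [
        (f"chr{int(rng.integers(1, 4))}", int(rng.integers(10_000, 10_000_000)),
         f"chr{int(rng.integers(4, 7))}", int(rng.integers(10_000, 10_000_000)))
        for _ in range(n_events)
    ]
    # enforce separation well beyond gamma so event identity is unambiguous
    centers = [
        c for i, c in enumerate(centers)
        if all(c[0] != d[0] or abs(c[1] - d[1]) > 5 * gamma for d in centers[:i])
    ]
    records = []
    callers = ["sniffles", "pbsv", "svim", "cutesv"]
    for k in range(n_records):
        c = centers[int(rng.integers(len(centers)))]
        records.append(
            TraRecord.canonical(
                c[0], c[1] + int(rng.integers(-gamma // 2, gamma // 2)),
                c[2], c[3] + int(rng.integers(-gamma // 2, gamma // 2)),
                caller=callers[int(rng.integers(4))],
            )
        )
    return records


class TestTra:
    def test_same_event_within_gamma(self):
        a = TraRecord("chr1", 1000, "chr5", 2000, "A")
        b = TraRecord("chr1", 1500, "chr5", 2500, "B")
        assert tra_same_event(a, b, 1000)

    def test_gamma_boundary_exact(self):
        a = TraRecord("chr1", 1000, "chr5", 2000, "A")
        assert tra_same_event(a, TraRecord("chr1", 1000, "chr5", 3000, "B"), 1000)
        assert not tra_same_event(a, TraRecord("chr1", 1000, "chr5", 3001, "B"), 1000)

    def test_chromosome_mismatch(self):
        a = TraRecord("chr1", 1000, "chr5", 2000, "A")
        b = TraRecord("chr1", 1000, "chr6", 2000, "B")
        assert not tra_same_event(a, b, 1000)

    @given(
        p1=st.integers(0, 10_000), p2=st.integers(0, 10_000),
        q1=st.integers(0, 10_000), q2=st.integers(0, 10_000),
        gamma=st.integers(1, 3000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_predicate_symmetric(self, p1, p2, q1, q2, gamma):
        a = TraRecord("chr1", p1, "chr2", p2, "A")
        b = TraRecord("chr1", q1, "chr2", q2, "B")
        assert tra_same_event(a, b, gamma) == tra_same_event(b, a, gamma)

    def test_support_threshold(self):
        recs = [TraRecord("chr1", 1000 + d, "chr5", 2000 + d, c)
                for d, c in [(0, "A"), (10, "B"), (20, "C")]]
        kept = merge_tras(recs, gamma=1000, c0=2)
        assert len(kept) == 1 and kept[0].support == 3

    def test_single_caller_dropped(self):
        assert merge_tras([TraRecord("chr1", 1000, "chr5", 2000, "A")], c0=2) == []

    def test_greedy_equals_transitive_closure_on_random_batteries(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            records = random_tra_records(rng)
            got = merge_tras(records, gamma=1000, c0=2)
            got_sets = {
                frozenset((m.chrom1, m.pos1, m.chrom2, m.pos2, m.caller) for m in cl.members)
                for cl in got
            }
            assert got_sets == closure_oracle(records, 1000, 2), f"seed {seed}"

    def test_output_partitions_kept_inputs(self):
        rng = np.random.default_rng(123)
        records = random_tra_records(rng)
        clusters = merge_tras(records, gamma=1000, c0=1)
        seen = [m for cl in clusters for m in cl.members]
        assert sorted(seen, key=lambda t: (t.chrom1, t.pos1, t.caller)) == sorted(
            records, key=lambda t: (t.chrom1, t.pos1, t.caller)
        )


class TestLabeling:
    def test_close_same_type_positive(self):
        cand = _del(1000, 100, id="c")
        truth = _del(1005, 97, id="t")
        (lc,) = label_candidates([cand], [truth], refdist=1000, pctsize=0.7)
        assert lc.label == "positive" and lc.matched_truth_id == "t"

    def test_type_mismatch_negative(self):
        cand = SVRecord("chr1", 1000, 1100, 100, "INV", id="c")
        truth = _del(1000, 100, id="t")
        (lc,) = label_candidates([cand], [truth])
        assert lc.label == "negative"

    def test_truth_matched_at_most_once(self):
        truth = [_del(1000, 100, id="t")]
        cands = [_del(1001, 100, id="near"), _del(1050, 100, id="far")]
        labeled = label_candidates(cands, truth)
        by_id = {l.record.id: l.label for l in labeled}
        assert by_id == {"near": "positive", "far": "negative"}

    def test_decoy_injection_recovered_exactly(self, small_sim):
        truth, _ = load_vcf(small_sim.truth_vcf, caller="truth")
        decoys, _ = load_vcf(small_sim.decoy_vcf, caller="decoy")
        labeled = label_candidates(truth + decoys, truth)
        for lc in labeled:
            expected = "negative" if lc.record.id.startswith("decoy") else "positive"
            assert lc.label == expected, lc.record.id
        assert sum(l.label == "positive" for l in labeled) + sum(
            l.label == "negative" for l in labeled
        ) == len(labeled)
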