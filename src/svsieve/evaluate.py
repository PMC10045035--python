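"""Precision / recall / F1 scoring of a candidate callset against a truth set.

The matcher is the same one used to label training samples
(:func:`svsieve.callset.label_candidates`): a candidate counts as a true
positive when a same-type truth record lies within ``refdist`` and the length
ratio is at least ``pctsize``, with one-to-one assignment. Then

    Pre = TP / (TP + FP),  Rec = TP / (TP + FN),  F1 = 2*Pre*Rec / (Pre + Rec).

Zero-denominator cases are reported as ``None`` (undefined), never as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .callset import (
    DEFAULT_PCTSIZE,
    DEFAULT_REFDIST,
    SVRecord,
    label_candidates,
)


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    per_type: dict[str, "EvalResult"] = field(default_factory=dict)

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)

    def to_dict(self) -> dict:
        d = {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }
        if self.per_type:
            d["per_type"] = {t: r.to_dict() for t, r in sorted(self.per_type.items())}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_table(self) -> str:
        def fmt(v):
            return "undef" if v is None else f"{100 * v:6.2f}"

        lines = [f"{'TYPE':<6} {'TP':>5} {'FP':>5} {'FN':>5} {'Pre%':>7} {'Rec%':>7} {'F1%':>7}"]
        rows = sorted(self.per_type.items()) + [("All", self)]
        for name, r in rows:
            lines.append(
                f"{name:<6} {r.tp:>5} {r.fp:>5} {r.fn:>5} "
                f"{fmt(r.precision):>7} {fmt(r.recall):>7} {fmt(r.f1):>7}"
            )
        return "\n".join(lines)


def counts_to_result(tp: int, fp: int, fn: int) -> EvalResult:
    return EvalResult(tp, fp, fn)


def score(
    candidates: Sequence[SVRecord],
    truth: Sequence[SVRecord],
    refdist: int = DEFAULT_REFDIST,
    pctsize: float = DEFAULT_PCTSIZE,
) -> EvalResult:
    """Score candidates against truth with the shared one-to-one matcher."""
    labeled = label_candidates(candidates, truth, refdist, pctsize)
    types = sorted({r.svtype for r in truth} | {r.svtype for r in candidates})
    per_type: dict[str, EvalResult] = {}
    total_tp = total_fp = total_fn = 0
    for svtype in types:
        tp = sum(1 for l in labeled if l.record.svtype == svtype and l.label == "positive")
        fp = sum(1 for l in labeled if l.record.svtype == svtype and l.label == "negative")
        n_truth = sum(1 for t in truth if t.svtype == svtype)
        fn = n_truth - tp
        per_type[svtype] = EvalResult(tp, fp, fn)
        total_tp += tp
        total_fp += fp
        total_fn += fn
    return EvalResult(total_tp, total_fp, total_fn, per_type)
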