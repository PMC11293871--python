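"""Micro-averaged evaluation of relation predictions against gold.

Matching follows the challenge-scorer convention: a prediction is a true
positive iff its exact tuple (doc_id, rtype, arg1, arg2) occurs in gold;
otherwise it is a false positive, and every unmatched gold tuple is a
false negative attributed to its relation type. Both sides are collapsed
to sets first, so duplicates never count twice.

Micro precision = sum(TP) / sum(TP + FP), micro recall =
sum(TP) / sum(TP + FN), and F1 is their harmonic mean. Metrics are
reported on the 0-100 scale. 0/0 conventions: a metric whose denominator
is zero is 0 when the opposing count is nonzero; when gold and
predictions are both empty the report says 100 with an explicit
``vacuous`` flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from dtre.corpus_io import RelationAnnotation
from dtre.relations import RELATION_TYPES


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class EvaluationReport:
    per_class: dict[str, dict[str, float]]
    micro: dict[str, float]
    vacuous: bool = False
    unreachable_gold: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": 1,
                "per_class": self.per_class,
                "micro": self.micro,
                "vacuous": self.vacuous,
                "unreachable_gold": self.unreachable_gold,
            },
            indent=1,
            sort_keys=True,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def match_predictions(
    gold: Iterable[RelationAnnotation],
    pred: Iterable[RelationAnnotation],
) -> dict[str, ClassCounts]:
    """Per-class TP/FP/FN from exact-tuple set matching."""
    gold_set = set(gold)
    pred_set = set(pred)
    counts = {r: ClassCounts() for r in RELATION_TYPES}
    for p in pred_set:
        if p in gold_set:
            counts[p.rtype].tp += 1
        else:
            counts[p.rtype].fp += 1
    for g in gold_set - pred_set:
        counts[g.rtype].fn += 1
    return counts


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = 100.0 * tp / (tp + fp) if (tp + fp) else 0.0
    recall = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return precision, recall, f1


def micro_f1(counts: Mapping[str, ClassCounts]) -> tuple[float, float, float]:
    """Pooled (micro-averaged) precision, recall and F1, on the 0-100 scale."""
    tp = sum(c.tp for c in counts.values())
    fp = sum(c.fp for c in counts.values())
    fn = sum(c.fn for c in counts.values())
    if tp == fp == fn == 0:
        return 100.0, 100.0, 100.0  # vacuously perfect; flagged in the report
    return _prf(tp, fp, fn)


def per_class_report(
    counts: Mapping[str, ClassCounts], unreachable_gold: int = 0
) -> EvaluationReport:
    """Per-class and micro metrics over the 13 relation classes."""
    per_class: dict[str, dict[str, float]] = {}
    for rtype in RELATION_TYPES:
        c = counts.get(rtype, ClassCounts())
        p, r, f = _prf(c.tp, c.fp, c.fn)
        per_class[rtype] = {
            "tp": c.tp,
            "fp": c.fp,
            "fn": c.fn,
            "precision": p,
            "recall": r,
            "f1": f,
            "empty": c.tp == c.fp == c.fn == 0,
        }
    total = sum(c.tp + c.fp + c.fn for c in counts.values())
    mp, mr, mf = micro_f1(counts)
    return EvaluationReport(
        per_class=per_class,
        micro={"precision": mp, "recall": mr, "f1": mf},
        vacuous=total == 0,
        unreachable_gold=unreachable_gold,
    )


def evaluate(
    gold: Sequence[RelationAnnotation],
    pred: Sequence[RelationAnnotation],
    unreachable_gold: int = 0,
) -> EvaluationReport:
    """Convenience: match then report."""
    return per_class_report(match_predictions(gold, pred), unreachable_gold)


def format_report(report: EvaluationReport) -> str:
    """Tabular text rendering, one decimal, matching challenge-style output."""
    lines = [f"{'class':<24}{'TP':>5}{'FP':>5}{'FN':>5}{'P':>8}{'R':>8}{'F1':>8}"]
    for rtype in RELATION_TYPES:
        m = report.per_class[rtype]
        lines.append(
            f"{rtype:<24}{m['tp']:>5}{m['fp']:>5}{m['fn']:>5}"
            f"{m['precision']:>8.1f}{m['recall']:>8.1f}{m['f1']:>8.1f}"
        )
    mic = report.micro
    lines.append(
        f"{'micro':<24}{'':>15}{mic['precision']:>8.1f}{mic['recall']:>8.1f}"
        f"{mic['f1']:>8.1f}"
    )
    if report.vacuous:
        lines.append("(no gold relations and no predictions: vacuously perfect)")
    if report.unreachable_gold:
        lines.append(
            f"unreachable gold relations (cross-sentence): {report.unreachable_gold}"
        )
    return "\n".join(lines)
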