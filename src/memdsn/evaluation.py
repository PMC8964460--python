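"""Per-class and overall evaluation of membrane-protein-type predictions.

Metrics follow the standard one-vs-rest tallies for each class c (predicting
c is "positive"): sensitivity SN = TP/(TP+FN), specificity SP = TN/(TN+FP),
accuracy ACC = (TP+TN)/n, and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).

When a denominator factor is zero the metric is defined as 0 (with a logged
warning) so batch reports never fail.  The per-class "accuracy" reported in
benchmark tables for this problem is the recall on that class's own test
members — x correct of y members — and the overall accuracy is the pooled
sum(correct)/sum(total); rendered percentages use one decimal, round half
up.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from memdsn.errors import ValidationError
from memdsn.pssm_io import AA_ORDER, ProteinSequence

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion tallies for a single class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ClassReport:
    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    correct: int
    total: int


@dataclass
class EvalReport:
    per_class: dict[int, ClassReport]
    overall_acc: float
    n_classes: int
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "per_class": {
                str(c): {
                    "counts": asdict(r.counts),
                    "sn": r.sn, "sp": r.sp, "acc": r.acc, "mcc": r.mcc,
                    "correct": r.correct, "total": r.total,
                    "percent": float(round_percent(r.correct, r.total)),
                }
                for c, r in self.per_class.items()
            },
            "overall_acc": self.overall_acc,
            "overall_percent": float(round_percent(
                sum(r.correct for r in self.per_class.values()),
                sum(r.total for r in self.per_class.values()) or 1,
            )),
            "n_classes": self.n_classes,
            "n_samples": self.n_samples,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def round_percent(correct: int, total: int) -> Decimal:
    """Percentage ``100*correct/total`` rounded to one decimal, half up."""
    if total == 0:
        return Decimal("0.0")
    return (Decimal(correct) * 100 / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)


def confusion_counts(y_true, y_pred, cls: int) -> ConfusionCounts:
    """One-vs-rest tally treating ``cls`` as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 1:
        raise ValueError("y_true and y_pred must be equal-length non-empty vectors")
    t = y_true == cls
    p = y_pred == cls
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def metrics_from_counts(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(SN, SP, ACC, MCC) from one-vs-rest tallies; degenerate denominators
    give 0 by convention."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    if c.tp + c.fn > 0:
        sn = c.tp / (c.tp + c.fn)
    else:
        logger.warning("SN undefined (no positives); reporting 0")
        sn = 0.0
    if c.tn + c.fp > 0:
        sp = c.tn / (c.tn + c.fp)
    else:
        logger.warning("SP undefined (no negatives); reporting 0")
        sp = 0.0
    acc = (c.tp + c.tn) / c.total
    denom = (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(denom))
    else:
        logger.warning("MCC undefined (zero denominator factor); reporting 0")
        mcc = 0.0
    return float(sn), float(sp), float(acc), float(mcc)


def build_report(y_true, y_pred, n_classes: int) -> EvalReport:
    """Full per-class + overall report in the benchmark-table convention:
    per-class correct/total over that class's own members, overall accuracy
    pooled over all samples."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        bad = (v < 1) | (v > n_classes)
        if bad.any():
            raise ValidationError(f"{name} holds labels outside [1, {n_classes}]")
    per_class = {}
    for c in range(1, n_classes + 1):
        counts = confusion_counts(y_true, y_pred, c)
        sn, sp, acc, mcc = metrics_from_counts(counts)
        total = int(np.sum(y_true == c))
        correct = int(np.sum((y_true == c) & (y_pred == c)))
        per_class[c] = ClassReport(counts, sn, sp, acc, mcc, correct, total)
    overall = float(np.mean(y_true == y_pred))
    return EvalReport(per_class=per_class, overall_acc=overall,
                      n_classes=n_classes, n_samples=len(y_true))


def render_table(report: EvalReport, class_names: dict[int, str] | None = None) -> str:
    """Benchmark-style text table: one row per class with 'percent (x/y)',
    plus an Overall row."""
    lines = [f"{'Class':<22}{'Accuracy':>16}"]
    for c, r in report.per_class.items():
        name = (class_names or {}).get(c, f"type {c}")
        lines.append(f"{name:<22}{str(round_percent(r.correct, r.total)):>8} ({r.correct}/{r.total})")
    correct = sum(r.correct for r in report.per_class.values())
    total = sum(r.total for r in report.per_class.values())
    lines.append(f"{'Overall':<22}{str(round_percent(correct, total)):>8} ({correct}/{total})")
    return "\n".join(lines)


def report_from_class_counts(counts: dict[int, tuple[int, int]]) -> EvalReport:
    """Build a report from per-class (correct, total) tallies alone, e.g. the
    printed columns of a benchmark table.  Misclassified members are assigned
    to an arbitrary other class; per-class recall and the overall accuracy do
    not depend on that choice."""
    n_classes = max(counts)
    y_true, y_pred = [], []
    for c, (correct, total) in counts.items():
        if not (0 <= correct <= total):
            raise ValueError(f"class {c}: correct {correct} outside [0, {total}]")
        other = c % n_classes + 1
        y_true += [c] * total
        y_pred += [c] * correct + [other] * (total - correct)
    return build_report(np.array(y_true), np.array(y_pred), n_classes)


def dataset_summary(sequences: list[ProteinSequence]) -> dict:
    """Per-class sequence-length quantiles and 20-letter amino-acid
    composition (frequencies sum to 1 per class; X residues are excluded
    from composition but counted in lengths)."""
    if not sequences:
        raise ValueError("empty sequence list")
    by_class: dict[int | None, list[ProteinSequence]] = {}
    for s in sequences:
        by_class.setdefault(s.label, []).append(s)
    out = {}
    for cls, seqs in sorted(by_class.items(), key=lambda kv: (kv[0] is None, kv[0])):
        lengths = np.array([len(s) for s in seqs])
        counts = np.zeros(20)
        for s in seqs:
            for ch in s.residues:
                if ch != "X":
                    counts[AA_ORDER.index(ch)] += 1
        comp = counts / counts.sum() if counts.sum() else counts
        out[cls if cls is not None else "unlabeled"] = {
            "n": len(seqs),
            "length": {
                "min": int(lengths.min()),
                "q1": float(np.percentile(lengths, 25)),
                "median": float(np.median(lengths)),
                "q3": float(np.percentile(lengths, 75)),
                "max": int(lengths.max()),
            },
            "composition": {aa: float(f) for aa, f in zip(AA_ORDER, comp)},
        }
    return out
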