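"""Evaluation machinery: binary gate metrics, per-class metrics and the
three-method unique-correct Venn attribution.

Conventions: "positive" means ROSes; recall and sensitivity are one
quantity; any metric with a zero denominator is reported as ``None``
(absent) with a warning, never coerced to 0.  Level-2 metrics are
computed only over examples whose true label is positive; a level-1
false negative surfaces there as a sentinel-class misprediction and
counts against the true class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    truth: Sequence[bool], predicted: Sequence[bool]
) -> ConfusionCounts:
    if len(truth) != len(predicted):
        raise EvaluationError("truth and prediction lengths differ")
    if len(truth) == 0:
        raise EvaluationError("nothing to evaluate")
    tp = fp = fn = tn = 0
    for t, p in zip(truth, predicted):
        if t and p:
            tp += 1
        elif t:
            fn += 1
        elif p:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as absent")
        return None
    return num / den


@dataclass
class BinaryMetrics:
    accuracy: float
    precision: float | None
    recall: float | None  # = sensitivity
    specificity: float | None
    f1: float | None
    n_evaluated: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "n_evaluated": self.n_evaluated,
        }


def binary_metrics(c: ConfusionCounts) -> BinaryMetrics:
    """Accuracy, precision, recall (=sensitivity), specificity, F1."""
    if c.total == 0:
        raise EvaluationError("empty confusion table")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
        if precision is not None and recall is not None:
            warnings.warn("f1 undefined (precision + recall = 0)")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return BinaryMetrics(
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        f1=f1,
        n_evaluated=c.total,
    )


@dataclass
class PerClassMetrics:
    """Per class: one-vs-rest accuracy and within-class recall."""

    accuracy: dict[str, float] = field(default_factory=dict)
    recall: dict[str, float | None] = field(default_factory=dict)


def per_class_recall(
    truth: Sequence[str],
    predicted: Sequence[str],
    class_names: Sequence[str],
    allow_extra_predicted: bool = False,
) -> PerClassMetrics:
    """Per-class recall (correct-in-class / truth-count) and one-vs-rest
    accuracy.  ``allow_extra_predicted`` admits out-of-set predictions
    (e.g. the sentinel emitted by the gate), which count as wrong."""
    if len(truth) != len(predicted):
        raise EvaluationError("truth and prediction lengths differ")
    known = set(class_names)
    for lbl in truth:
        if lbl not in known:
            raise EvaluationError(f"unknown truth class {lbl!r}")
    if not allow_extra_predicted:
        for lbl in predicted:
            if lbl not in known:
                raise EvaluationError(f"unknown predicted class {lbl!r}")
    out = PerClassMetrics()
    n = len(truth)
    for c in class_names:
        in_c = [i for i in range(n) if truth[i] == c]
        correct_in_c = sum(1 for i in in_c if predicted[i] == c)
        agree = sum(
            1 for i in range(n) if (truth[i] == c) == (predicted[i] == c)
        )
        out.accuracy[c] = agree / n if n else 0.0
        out.recall[c] = _ratio(correct_in_c, len(in_c), f"recall[{c}]")
    return out


def multiclass_accuracy(truth: Sequence[str], predicted: Sequence[str]) -> float:
    if len(truth) != len(predicted) or not truth:
        raise EvaluationError("truth and prediction lengths differ or empty")
    return sum(t == p for t, p in zip(truth, predicted)) / len(truth)


@dataclass(frozen=True)
class VennAttribution:
    """Counts of the 7 correctness regions for methods A, B, C plus the
    all-wrong remainder; always sums to the universe size."""

    only_a: int
    only_b: int
    only_c: int
    ab_not_c: int
    ac_not_b: int
    bc_not_a: int
    all_three: int
    none: int

    @property
    def total(self) -> int:
        return (
            self.only_a + self.only_b + self.only_c + self.ab_not_c
            + self.ac_not_b + self.bc_not_a + self.all_three + self.none
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "only_a": self.only_a,
            "only_b": self.only_b,
            "only_c": self.only_c,
            "ab_not_c": self.ab_not_c,
            "ac_not_b": self.ac_not_b,
            "bc_not_a": self.bc_not_a,
            "all_three": self.all_three,
            "none": self.none,
        }


def format_metrics_table(metrics: BinaryMetrics) -> str:
    """Fixed-width human-readable rendering of the binary metrics."""
    rows = [("n evaluated", str(metrics.n_evaluated))]
    for name in ("accuracy", "precision", "recall", "specificity", "f1"):
        value = getattr(metrics, name)
        rows.append((name, "absent" if value is None else f"{value:.4f}"))
    width = max(len(k) for k, _ in rows)
    return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def unique_correct_attribution(
    correct_a: set,
    correct_b: set,
    correct_c: set,
    universe: set,
) -> VennAttribution:
    """Partition the universe by which of the three methods got each
    example right."""
    for name, s in (("A", correct_a), ("B", correct_b), ("C", correct_c)):
        extra = s - universe
        if extra:
            raise EvaluationError(
                f"correct set {name} contains ids outside the universe: "
                f"{sorted(extra)[:3]}"
            )
    a, b, c = correct_a, correct_b, correct_c
    return VennAttribution(
        only_a=len(a - b - c),
        only_b=len(b - a - c),
        only_c=len(c - a - b),
        ab_not_c=len((a & b) - c),
        ac_not_b=len((a & c) - b),
        bc_not_a=len((b & c) - a),
        all_three=len(a & b & c),
        none=len(universe - a - b - c),
    )
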