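"""Detection evaluation: IoU matching, per-class tallies, metrics, confusion.

Detections are matched one-to-one to ground-truth annotations by IoU
(Jaccard index) at a 50% default overlap threshold, greedily in
descending confidence order.  Class labels are *not* required to agree
at match time: a detection that overlaps an annotation of another class
produces a cross-class confusion-matrix entry, counting as a false
positive for the predicted class and a false negative for the true
class.

Per class the metrics are (in percent)::

    precision  = 100 * TP / (TP + FP)
    recall     = 100 * TP / (TP + FN)
    F1         = 100 * 2*TP / (2*TP + FP + FN)
    error rate = 100 * (FP + FN) / (FP + FN + TP + TN)

with TN = 0 by convention — an object detector has no natural count of
true negatives.  All percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from flockwatch.boxes import BoundingBox
from flockwatch.classify import Annotation, Detection, ObjectClass

DEFAULT_IOU_THRESHOLD = 0.5


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator is zero for a class."""


def round_percent(numerator: int | float, denominator: int | float) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union (Jaccard index) of two pixel boxes."""
    inter = a.intersection_area(b)
    if inter == 0:
        return 0.0
    return inter / a.union_area(b)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one-to-one detection/annotation matching.

    ``pairs`` holds (detection index, annotation index, IoU) triples;
    indices not appearing in any pair are listed as unmatched.
    """

    pairs: tuple[tuple[int, int, float], ...]
    unmatched_detections: tuple[int, ...]
    unmatched_annotations: tuple[int, ...]


def match_detections(
    detections: Sequence[Detection],
    annotations: Sequence[Annotation],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Greedy one-to-one matching in descending detection confidence.

    Each detection, taken from highest confidence to lowest (ties broken
    by input order), claims the free annotation with the highest IoU,
    provided that IoU >= ``iou_threshold``; IoU ties go to the lower
    annotation index.  Labels play no role here.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1], got {iou_threshold}")
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].confidence, i))
    free = set(range(len(annotations)))
    pairs: list[tuple[int, int, float]] = []
    unmatched_det: list[int] = []
    for di in order:
        best_ai, best_iou = None, 0.0
        for ai in free:
            v = iou(detections[di].box, annotations[ai].box)
            if v >= iou_threshold and (
                v > best_iou or (v == best_iou and best_ai is not None and ai < best_ai)
            ):
                best_ai, best_iou = ai, v
        if best_ai is None:
            unmatched_det.append(di)
        else:
            free.remove(best_ai)
            pairs.append((di, best_ai, best_iou))
    return MatchResult(
        pairs=tuple(sorted(pairs)),
        unmatched_detections=tuple(sorted(unmatched_det)),
        unmatched_annotations=tuple(sorted(free)),
    )


@dataclass(frozen=True)
class ClassCounts:
    """GT/TP/FP/FN(/TN) object tallies for one class.

    The ground-truth total is always tp + fn; passing ``gt`` explicitly
    is allowed as a consistency check.  ``tn`` defaults to 0 — see the
    module docstring.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    gt: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.gt is None:
            object.__setattr__(self, "gt", self.tp + self.fn)
        elif self.gt != self.tp + self.fn:
            raise ValueError(
                f"inconsistent counts: gt={self.gt} but tp + fn = {self.tp + self.fn}"
            )


def tally_counts(
    match: MatchResult,
    detections: Sequence[Detection],
    annotations: Sequence[Annotation],
) -> dict[ObjectClass, ClassCounts]:
    """Per-class GT/TP/FP/FN tallies from a match result.

    For class c: TP = matched pairs where both labels are c; FN =
    annotations of c that are unmatched or matched by a detection of
    another label; FP = detections labeled c that are unmatched or
    matched to an annotation of another label.  TN = 0.
    """
    tp = {c: 0 for c in ObjectClass}
    fp = {c: 0 for c in ObjectClass}
    fn = {c: 0 for c in ObjectClass}
    for di, ai, _ in match.pairs:
        pred, true = detections[di].label, annotations[ai].label
        if pred is true:
            tp[pred] += 1
        else:
            fp[pred] += 1
            fn[true] += 1
    for di in match.unmatched_detections:
        fp[detections[di].label] += 1
    for ai in match.unmatched_annotations:
        fn[annotations[ai].label] += 1
    return {c: ClassCounts(tp=tp[c], fp=fp[c], fn=fn[c]) for c in ObjectClass}


def precision(c: ClassCounts) -> float:
    """Share of detections of the class that are correct, in percent."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no detections of this class")
    return round_percent(c.tp, c.tp + c.fp)


def recall(c: ClassCounts) -> float:
    """Share of ground-truth objects of the class found, in percent."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no ground-truth objects of this class")
    return round_percent(c.tp, c.tp + c.fn)


def f1_score(c: ClassCounts) -> float:
    """Harmonic mean of precision and recall, in percent."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise UndefinedMetricError("F1 undefined: no detections and no ground truth")
    return round_percent(2 * c.tp, denom)


def error_rate(c: ClassCounts) -> float:
    """Misclassified share of all counted objects of the class, in percent."""
    denom = c.fp + c.fn + c.tp + c.tn
    if denom == 0:
        raise UndefinedMetricError("error rate undefined: all counts are zero")
    return round_percent(c.fp + c.fn, denom)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Matched-pair label combinations plus out-of-class false positives.

    ``counts[(g, p)]`` is the number of annotations of true class g
    matched by detections of predicted class p; ``out_of_class_fp[p]``
    counts detections of class p that matched no annotation at all.
    """

    counts: dict[tuple[ObjectClass, ObjectClass], int] = field(default_factory=dict)
    out_of_class_fp: dict[ObjectClass, int] = field(default_factory=dict)

    def cell(self, true: ObjectClass, predicted: ObjectClass) -> int:
        return self.counts.get((true, predicted), 0)

    def to_frame(self) -> pd.DataFrame:
        """Class-by-class table with an extra out-of-class row."""
        classes = list(ObjectClass)
        data = {
            p.value: [self.cell(g, p) for g in classes] for p in classes
        }
        df = pd.DataFrame(data, index=[g.value for g in classes])
        df.loc["(none)"] = [self.out_of_class_fp.get(p, 0) for p in classes]
        df.index.name = "ground_truth"
        return df


def confusion_matrix(
    match: MatchResult,
    detections: Sequence[Detection],
    annotations: Sequence[Annotation],
) -> ConfusionMatrix:
    counts: dict[tuple[ObjectClass, ObjectClass], int] = {}
    out_fp: dict[ObjectClass, int] = {c: 0 for c in ObjectClass}
    for di, ai, _ in match.pairs:
        key = (annotations[ai].label, detections[di].label)
        counts[key] = counts.get(key, 0) + 1
    for di in match.unmatched_detections:
        out_fp[detections[di].label] += 1
    return ConfusionMatrix(counts=counts, out_of_class_fp=out_fp)


def metrics_table(counts: dict[ObjectClass, ClassCounts]) -> pd.DataFrame:
    """Per-class report: counts plus the four metrics (NaN if undefined)."""
    rows = []
    for c, cc in counts.items():
        row: dict[str, object] = {
            "class": c.value,
            "gt": cc.gt,
            "tp": cc.tp,
            "fp": cc.fp,
            "fn": cc.fn,
        }
        for name, fn in (
            ("precision", precision),
            ("recall", recall),
            ("f1", f1_score),
            ("error_rate", error_rate),
        ):
            try:
                row[name] = fn(cc)
            except UndefinedMetricError:
                row[name] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


def evaluate_detections(
    detections: Sequence[Detection],
    annotations: Sequence[Annotation],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> tuple[pd.DataFrame, ConfusionMatrix]:
    """Full evaluation: match, tally, metric table, confusion matrix."""
    match = match_detections(detections, annotations, iou_threshold)
    counts = tally_counts(match, detections, annotations)
    return metrics_table(counts), confusion_matrix(match, detections, annotations)


def write_report(
    table: pd.DataFrame, confusion: ConfusionMatrix, report_path: str | Path, confusion_path: str | Path
) -> None:
    table.to_csv(report_path)
    confusion.to_frame().to_csv(confusion_path)
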