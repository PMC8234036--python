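"""Benchmark tallies from the vineyard field trial of the detector.

The deployed system's classifier was scored on a held-out test set of
134 annotated images containing 1008 ground-truth objects across the
four classes.  The per-class GT/TP/FN/FP tallies and the cross-class
confusion cells below are the published benchmark of that trial; they
are inputs to the evaluation formulas, useful for regression-checking
the metric implementations and for constructing abstract fixtures with
:func:`flockwatch.simulate.make_fixture_from_counts`.

Two printed precision/F1 cells of the trial report (bird 83.4%, bug
65.8%/66.7%) do not follow from these tallies under the standard
formulas (which give bird 83.8%/83.6% and bug 66.7%/67.1%); the
reconcilable cells are all recalls, all error rates, and the flock and
helicopter precision/F1 values.  :data:`RECONCILABLE_METRICS` lists
them.
"""

from __future__ import annotations

from flockwatch.classify import ObjectClass
from flockwatch.evaluation import ClassCounts, ConfusionMatrix

#: Per-class GT/TP/FN/FP object tallies of the field-trial test set.
FIELD_TRIAL_COUNTS: dict[ObjectClass, ClassCounts] = {
    ObjectClass.BIRD: ClassCounts(tp=749, fn=149, fp=145, gt=898),
    ObjectClass.BUG: ClassCounts(tp=48, fn=23, fp=24, gt=71),
    ObjectClass.FLOCK: ClassCounts(tp=33, fn=2, fp=0, gt=35),
    ObjectClass.HELICOPTER: ClassCounts(tp=4, fn=0, fp=0, gt=4),
}

#: Matched-pair label combinations (true class, predicted class) and the
#: out-of-class false positives — detections overlapping no annotation.
FIELD_TRIAL_CONFUSION = ConfusionMatrix(
    counts={
        (ObjectClass.BIRD, ObjectClass.BIRD): 749,
        (ObjectClass.BIRD, ObjectClass.BUG): 1,
        (ObjectClass.BUG, ObjectClass.BIRD): 3,
        (ObjectClass.BUG, ObjectClass.BUG): 48,
        (ObjectClass.FLOCK, ObjectClass.BIRD): 1,
        (ObjectClass.FLOCK, ObjectClass.FLOCK): 33,
        (ObjectClass.HELICOPTER, ObjectClass.HELICOPTER): 4,
    },
    out_of_class_fp={
        ObjectClass.BIRD: 141,
        ObjectClass.BUG: 23,
        ObjectClass.FLOCK: 0,
        ObjectClass.HELICOPTER: 0,
    },
)

#: Metric cells of the trial report that the formulas reproduce from the
#: tallies; the remaining cells (bird/bug precision and F1) were reported
#: by the external training service and do not reconcile — see module
#: docstring.
RECONCILABLE_METRICS: tuple[tuple[ObjectClass, str], ...] = (
    *((c, "recall") for c in ObjectClass),
    *((c, "error_rate") for c in ObjectClass),
    (ObjectClass.FLOCK, "precision"),
    (ObjectClass.FLOCK, "f1"),
    (ObjectClass.HELICOPTER, "precision"),
    (ObjectClass.HELICOPTER, "f1"),
)


def total_ground_truth() -> int:
    """Total annotated objects in the field-trial test set (1008)."""
    return sum(cc.gt for cc in FIELD_TRIAL_COUNTS.values())
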