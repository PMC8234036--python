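"""IoU, matching, tallies, the four metrics, and the confusion matrix."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from flockwatch.boxes import BoundingBox
from flockwatch.classify import Annotation, Detection, ObjectClass
from flockwatch.evaluation import (
    ClassCounts,
    UndefinedMetricError,
    confusion_matrix,
    error_rate,
    evaluate_detections,
    f1_score,
    iou,
    match_detections,
    precision,
    recall,
    round_percent,
    tally_counts,
)
from flockwatch.fieldstudy import FIELD_TRIAL_CONFUSION, FIELD_TRIAL_COUNTS
from flockwatch.simulate import make_fixture_from_counts

boxes_strategy = st.builds(
    lambda x, y, w, h: BoundingBox(x, y, x + w, y + h),
    st.integers(0, 20), st.integers(0, 20), st.integers(1, 10), st.integers(1, 10),
)


def det(box, label=ObjectClass.BIRD, conf=0.8):
    return Detection(box=box, label=label, confidence=conf)


def ann(box, label=ObjectClass.BIRD):
    return Annotation(box=box, label=label)


class TestIoU:
    def test_identical_boxes(self):
        b = BoundingBox(2, 3, 7, 9)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(5, 5, 7, 7)) == 0.0

    def test_edge_touching_boxes_are_disjoint(self):
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(2, 0, 4, 2)) == 0.0

    def test_unit_overlap(self):
        # pixel-counting oracle: intersection 1, union 4 + 4 - 1 = 7
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(1, 1, 3, 3)) == pytest.approx(1 / 7)

    @given(boxes_strategy, boxes_strategy)
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0
        # brute-force pixel counting oracle
        pa = {(x, y) for x in range(a.x0, a.x1) for y in range(a.y0, a.y1)}
        pb = {(x, y) for x in range(b.x0, b.x1) for y in range(b.y0, b.y1)}
        assert v == pytest.approx(len(pa & pb) / len(pa | pb))


class TestMatchDetections:
    def test_empty_inputs(self):
        m = match_detections([], [])
        assert m.pairs == () and m.unmatched_detections == () and m.unmatched_annotations == ()

    def test_exact_overlap_matches(self):
        b = BoundingBox(0, 0, 4, 4)
        m = match_detections([det(b)], [ann(b)])
        assert m.pairs == ((0, 0, 1.0),)

    def test_confident_detection_wins_contested_annotation(self):
        b = BoundingBox(0, 0, 4, 4)
        dets = [det(b, conf=0.4), det(b, conf=0.9)]
        m = match_detections(dets, [ann(b)])
        assert m.pairs == ((1, 0, 1.0),)
        assert m.unmatched_detections == (0,)

    def test_below_threshold_not_matched(self):
        m = match_detections(
            [det(BoundingBox(0, 0, 2, 2))], [ann(BoundingBox(1, 1, 3, 3))], iou_threshold=0.5
        )
        assert m.pairs == ()

    def test_greedy_matches_exhaustive_assignment_on_small_instances(self):
        """On <=3x3 instances greedy agrees with the best exhaustive
        assignment that respects confidence priority."""
        grid = [BoundingBox(0, 0, 4, 4), BoundingBox(2, 0, 6, 4), BoundingBox(0, 2, 4, 6)]
        dets = [det(b, conf=c) for b, c in zip(grid, (0.9, 0.7, 0.5))]
        anns = [ann(b) for b in grid]
        m = match_detections(dets, anns)
        # oracle: assign in confidence order, each detection takes its best free annotation
        free = set(range(3))
        expected = []
        for di in (0, 1, 2):
            cands = [(iou(dets[di].box, anns[ai].box), -ai, ai) for ai in free]
            v, _, ai = max(cands)
            if v >= 0.5:
                expected.append((di, ai, v))
                free.remove(ai)
        assert sorted(m.pairs) == sorted(expected)

    def test_label_disagreement_still_matches(self):
        b = BoundingBox(0, 0, 4, 4)
        m = match_detections([det(b, ObjectClass.BIRD)], [ann(b, ObjectClass.FLOCK)])
        assert len(m.pairs) == 1

    def test_stable_under_permutation_with_distinct_confidences(self):
        boxes = [BoundingBox(6 * i, 0, 6 * i + 4, 4) for i in range(4)]
        dets = [det(b, conf=0.9 - 0.1 * i) for i, b in enumerate(boxes)]
        anns = [ann(b) for b in boxes]
        base = match_detections(dets, anns)
        for perm in itertools.permutations(range(4)):
            pd = [dets[i] for i in perm]
            m = match_detections(pd, anns)
            matched = {(pd[di].box, ai) for di, ai, _ in m.pairs}
            assert matched == {(dets[di].box, ai) for di, ai, _ in base.pairs}


class TestTallyAndConfusion:
    def test_perfect_detector(self):
        anns = [ann(BoundingBox(8 * i, 0, 8 * i + 4, 4),
                    [ObjectClass.BIRD, ObjectClass.BUG, ObjectClass.FLOCK][i % 3])
                for i in range(6)]
        dets = [det(a.box, a.label) for a in anns]
        m = match_detections(dets, anns)
        counts = tally_counts(m, dets, anns)
        for c, cc in counts.items():
            assert cc.fp == 0 and cc.fn == 0 and cc.tp == cc.gt
        cm = confusion_matrix(m, dets, anns)
        for c in ObjectClass:
            assert cm.cell(c, c) == counts[c].gt
            assert all(cm.cell(c, p) == 0 for p in ObjectClass if p is not c)

    def test_cross_class_match_is_fp_and_fn(self):
        """One flock annotation matched by a bird detection plus one missed
        flock: tp 33 analogue at small scale -> tp 0, fn 2, bird fp 1."""
        f1, f2 = BoundingBox(0, 0, 4, 4), BoundingBox(10, 10, 14, 14)
        anns = [ann(f1, ObjectClass.FLOCK), ann(f2, ObjectClass.FLOCK)]
        dets = [det(f1, ObjectClass.BIRD)]
        m = match_detections(dets, anns)
        counts = tally_counts(m, dets, anns)
        assert counts[ObjectClass.FLOCK] == ClassCounts(tp=0, fp=0, fn=2)
        assert counts[ObjectClass.BIRD] == ClassCounts(tp=0, fp=1, fn=0)

    def test_lone_false_positive(self):
        dets = [det(BoundingBox(0, 0, 3, 3), ObjectClass.BIRD)]
        counts = tally_counts(match_detections(dets, []), dets, [])
        assert counts[ObjectClass.BIRD].fp == 1
        assert all(cc.tp == cc.fn == 0 for cc in counts.values())

    def test_field_trial_flock_row(self):
        """35 flock GT: 33 correct, 1 matched by a bird detection, 1 missed."""
        dets, anns = make_fixture_from_counts(FIELD_TRIAL_COUNTS, FIELD_TRIAL_CONFUSION)
        m = match_detections(dets, anns)
        counts = tally_counts(m, dets, anns)
        assert counts[ObjectClass.FLOCK] == ClassCounts(tp=33, fp=0, fn=2, gt=35)
        cm = confusion_matrix(m, dets, anns)
        assert [cm.cell(ObjectClass.BUG, p) for p in ObjectClass] == [3, 48, 0, 0]
        # bird FP decomposition: 145 total = 4 cross-class + 141 out-of-class
        cross = sum(cm.cell(g, ObjectClass.BIRD) for g in ObjectClass if g is not ObjectClass.BIRD)
        assert cross == 4
        assert cm.out_of_class_fp[ObjectClass.BIRD] == 141
        assert counts[ObjectClass.BIRD].fp == cross + 141


class TestMetrics:
    @pytest.mark.parametrize(
        "fn,counts,expected",
        [
            (precision, ClassCounts(tp=33, fp=0, fn=2), 100.0),
            (precision, ClassCounts(tp=1, fp=1), 50.0),
            (precision, ClassCounts(tp=4, fp=0), 100.0),
            (recall, ClassCounts(tp=33, fn=2), 94.3),
            (recall, ClassCounts(tp=749, fn=149), 83.4),
            (recall, ClassCounts(tp=7, fn=0), 100.0),
            (f1_score, ClassCounts(tp=33, fp=0, fn=2), 97.1),
            (f1_score, ClassCounts(tp=0, fp=1, fn=1), 0.0),
            (f1_score, ClassCounts(tp=3, fp=1, fn=1), 75.0),  # P = R => F1 = P
            (error_rate, ClassCounts(tp=33, fp=0, fn=2), 5.7),
            (error_rate, ClassCounts(tp=749, fp=145, fn=149), 28.2),
            (error_rate, ClassCounts(tp=5, fp=0, fn=0), 0.0),
        ],
    )
    def test_formula_values(self, fn, counts, expected):
        assert fn(counts) == expected

    def test_undefined_metrics_raise(self):
        empty = ClassCounts()
        for fn in (precision, recall, f1_score, error_rate):
            with pytest.raises(UndefinedMetricError):
                fn(empty)

    def test_gt_consistency_enforced(self):
        with pytest.raises(ValueError, match="gt"):
            ClassCounts(tp=3, fn=1, gt=5)

    def test_rounding_is_half_up(self):
        assert round_percent(1, 16) == 6.3  # 6.25 rounds up, not to even
        assert round_percent(33, 35) == 94.3
        assert round_percent(749, 898) == 83.4

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_f1_between_precision_and_recall(self, tp, fp, fn):
        c = ClassCounts(tp=tp, fp=fp, fn=fn)
        try:
            p, r, f = precision(c), recall(c), f1_score(c)
        except UndefinedMetricError:
            return
        assert 0.0 <= f <= 100.0
        # rounded to one decimal, so allow half-unit slack at the bounds
        assert min(p, r) - 0.05 <= f <= max(p, r) + 0.05


class TestFullEvaluation:
    def test_reproduces_field_trial_reconcilable_cells(self):
        """The full pipeline on the trial-count fixture returns every
        reconcilable report cell: all recalls and error rates, and the
        flock/helicopter precision and F1 values."""
        dets, anns = make_fixture_from_counts(FIELD_TRIAL_COUNTS, FIELD_TRIAL_CONFUSION)
        table, cm = evaluate_detections(dets, anns)
        expected = {
            "bird": {"recall": 83.4, "error_rate": 28.2},
            "bug": {"recall": 67.6, "error_rate": 49.5},
            "flock": {"recall": 94.3, "error_rate": 5.7, "precision": 100.0, "f1": 97.1},
            "helicopter": {"recall": 100.0, "error_rate": 0.0, "precision": 100.0, "f1": 100.0},
        }
        for cls, cells in expected.items():
            for metric, value in cells.items():
                assert table.loc[cls, metric] == value, (cls, metric)
        assert int(table["gt"].sum()) == 1008
        for c in ObjectClass:
            assert table.loc[c.value, "tp"] + table.loc[c.value, "fn"] == table.loc[c.value, "gt"]
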