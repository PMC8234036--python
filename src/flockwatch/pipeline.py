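"""End-to-end composition: motion detection → classification → evaluation.

Glue for running a whole frame sequence through the detector and a
classifier, and for scoring the resulting per-frame detections against
per-frame ground truth.  Frame 0 never yields detections (the detector
needs a previous frame), so sequence-level scoring starts at frame 1.
"""

from __future__ import annotations

from typing import Sequence

from flockwatch.classify import Annotation, Classifier, Detection, ObjectClass
from flockwatch.evaluation import (
    ClassCounts,
    match_detections,
    tally_counts,
)
from flockwatch.motion import Frame, MotionConfig, MotionDetector


def detect_and_classify(
    frames: Sequence[Frame],
    classifier: Classifier,
    motion_config: MotionConfig | None = None,
) -> list[list[Detection]]:
    """Run the detector then the classifier on every frame."""
    detector = MotionDetector(config=motion_config or MotionConfig())
    out: list[list[Detection]] = []
    for frame in frames:
        boxes, _ = detector.process(frame)
        out.append(classifier.classify(frame, boxes) if boxes else [])
    return out


def score_sequence(
    per_frame_detections: Sequence[Sequence[Detection]],
    per_frame_annotations: Sequence[Sequence[Annotation]],
    iou_threshold: float = 0.5,
    start_frame: int = 1,
) -> dict[ObjectClass, ClassCounts]:
    """Aggregate per-class tallies over frames ``start_frame`` onward."""
    if len(per_frame_detections) != len(per_frame_annotations):
        raise ValueError(
            f"sequence length mismatch: {len(per_frame_detections)} detection frames "
            f"vs {len(per_frame_annotations)} annotation frames"
        )
    tp = {c: 0 for c in ObjectClass}
    fp = {c: 0 for c in ObjectClass}
    fn = {c: 0 for c in ObjectClass}
    for dets, anns in zip(
        per_frame_detections[start_frame:], per_frame_annotations[start_frame:]
    ):
        match = match_detections(list(dets), list(anns), iou_threshold)
        for c, cc in tally_counts(match, list(dets), list(anns)).items():
            tp[c] += cc.tp
            fp[c] += cc.fp
            fn[c] += cc.fn
    return {c: ClassCounts(tp=tp[c], fp=fp[c], fn=fn[c]) for c in ObjectClass}
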