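"""Object taxonomy, classifier contract, and flock grouping.

The field system distinguishes four evaluation classes: individual
*birds*, near-camera *bugs* (insects are the dominant false-alarm source
for frame differencing), *flocks* — five or more birds flying together,
the only class allowed to fire the scaring actuator — and *helicopters*
(large, slow airborne objects).

Any classifier satisfying :class:`Classifier` can be plugged into the
pipeline; :class:`HeuristicClassifier` is a simple size-and-context
reference used for end-to-end testing of the surrounding machinery.  It
is a stand-in with hand-set rules, not a trained model, and makes no
claim about accuracy on field imagery.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

from flockwatch.boxes import BoundingBox, hull_of
from flockwatch.motion import Frame

#: Minimum number of birds flying together that constitutes a flock.
FLOCK_MIN_BIRDS = 5


class ObjectClass(enum.StrEnum):
    """Closed set of evaluation classes."""

    BIRD = "bird"
    BUG = "bug"
    FLOCK = "flock"
    HELICOPTER = "helicopter"


@dataclass(frozen=True)
class Detection:
    """A classified box with the classifier's confidence score in [0, 1]."""

    box: BoundingBox
    label: ObjectClass
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")
        object.__setattr__(self, "label", ObjectClass(self.label))


@dataclass(frozen=True)
class Annotation:
    """A ground-truth box with its human-assigned class label."""

    box: BoundingBox
    label: ObjectClass

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", ObjectClass(self.label))


class Classifier(Protocol):
    """Contract every pluggable object classifier must satisfy.

    Implementations may emit flock boxes directly or emit per-bird boxes
    and rely on :func:`group_flocks` downstream; both paths are
    supported by the pipeline.
    """

    def classify(
        self, frame: Frame, candidate_boxes: Sequence[BoundingBox]
    ) -> list[Detection]: ...


def _check_in_bounds(frame: Frame, boxes: Sequence[BoundingBox]) -> None:
    for b in boxes:
        if b.x0 < 0 or b.y0 < 0 or b.x1 > frame.width or b.y1 > frame.height:
            raise ValueError(
                f"candidate box {b.as_list()} lies outside frame bounds "
                f"{frame.width}x{frame.height}"
            )


@dataclass
class HeuristicClassifier:
    """Size-and-context reference classifier.

    Per-box rules: a blob of at most ``bug_max_area`` pixels is a bug
    (insects close to the lens image as one or two pixels), a blob of at
    least ``helicopter_min_area`` pixels is a helicopter, anything in
    between is a bird.  Bird detections closer together than the flock
    proximity are then grouped; clusters of five or more become a single
    flock detection.  Confidence grows with blob area (birds and bugs)
    and, for flocks, is the mean of the member confidences.
    """

    bug_max_area: int = 2
    helicopter_min_area: int = 225
    flock_proximity: float | None = None  # None -> adaptive default

    def classify(
        self, frame: Frame, candidate_boxes: Sequence[BoundingBox]
    ) -> list[Detection]:
        _check_in_bounds(frame, candidate_boxes)
        singles: list[Detection] = []
        for box in candidate_boxes:
            if box.area <= self.bug_max_area:
                label = ObjectClass.BUG
                conf = 0.35 + 0.05 * box.area
            elif box.area >= self.helicopter_min_area:
                label = ObjectClass.HELICOPTER
                conf = min(0.95, 0.5 + box.area / 2000.0)
            else:
                label = ObjectClass.BIRD
                conf = min(0.9, 0.3 + 0.02 * box.area)
            singles.append(Detection(box=box, label=label, confidence=round(conf, 4)))
        return group_flocks(singles, proximity=self.flock_proximity)


def default_flock_proximity(bird_detections: Sequence[Detection]) -> float:
    """Adaptive grouping distance: 4x the median bird-box diagonal.

    Birds of one flock are imaged at a similar distance, so their
    apparent size sets the natural spatial scale for "flying together".
    """
    diags = [np.hypot(d.box.width, d.box.height) for d in bird_detections]
    if not diags:
        return 1.0
    return 4.0 * float(np.median(diags))


def group_flocks(
    detections: Sequence[Detection], proximity: float | None = None
) -> list[Detection]:
    """Merge clustered bird detections into flock detections.

    Single-linkage clustering of bird boxes whose center-to-center
    distance is at most ``proximity``: every cluster of
    :data:`FLOCK_MIN_BIRDS` (five) or more birds is replaced by one
    flock detection whose box is the cluster hull and whose confidence
    is the mean member confidence; smaller clusters pass through
    unchanged, as do non-bird detections.  No object is ever lost.
    """
    birds = [d for d in detections if d.label is ObjectClass.BIRD]
    others = [d for d in detections if d.label is not ObjectClass.BIRD]
    if proximity is None:
        proximity = default_flock_proximity(birds)
    if proximity <= 0:
        raise ValueError(f"proximity must be positive, got {proximity}")

    # Single linkage = connected components of the "within proximity" graph.
    n = len(birds)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    centers = [b.box.center for b in birds]
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1]) <= proximity:
                parent[find(i)] = find(j)

    clusters: dict[int, list[Detection]] = {}
    for i, bird in enumerate(birds):
        clusters.setdefault(find(i), []).append(bird)

    out = list(others)
    # Deterministic output order regardless of input permutation.
    for members in sorted(
        clusters.values(), key=lambda ms: min((m.box.y0, m.box.x0) for m in ms)
    ):
        if len(members) >= FLOCK_MIN_BIRDS:
            out.append(
                Detection(
                    box=hull_of(m.box for m in members),
                    label=ObjectClass.FLOCK,
                    confidence=float(np.mean([m.confidence for m in members])),
                )
            )
        else:
            out.extend(members)
    out.sort(key=lambda d: (d.box.y0, d.box.x0, d.label.value))
    return out


# --- annotation / detection file formats ------------------------------------
#
# JSON: a list of {"box": [x0, y0, x1, y1], "label": "bird", ...}; detections
# additionally carry "confidence".  CSV: columns image,x0,y0,x1,y1,label.


def read_annotations_json(path: str | Path) -> list[Annotation]:
    records = json.loads(Path(path).read_text())
    return [
        Annotation(box=BoundingBox.from_sequence(r["box"]), label=ObjectClass(r["label"]))
        for r in records
    ]


def write_annotations_json(annotations: Iterable[Annotation], path: str | Path) -> None:
    records = [{"box": a.box.as_list(), "label": a.label.value} for a in annotations]
    Path(path).write_text(json.dumps(records, indent=1))


def read_annotations_csv(path: str | Path) -> dict[str, list[Annotation]]:
    """Per-image annotations from a CSV with columns image,x0,y0,x1,y1,label."""
    out: dict[str, list[Annotation]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ann = Annotation(
                box=BoundingBox(int(row["x0"]), int(row["y0"]), int(row["x1"]), int(row["y1"])),
                label=ObjectClass(row["label"]),
            )
            out.setdefault(row["image"], []).append(ann)
    return out


def write_annotations_csv(per_image: dict[str, list[Annotation]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "x0", "y0", "x1", "y1", "label"])
        for image in sorted(per_image):
            for a in per_image[image]:
                writer.writerow([image, *a.box.as_list(), a.label.value])
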