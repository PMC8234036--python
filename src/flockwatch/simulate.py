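"""Seeded synthetic vineyard scenes with ground-truth annotations.

The generator emulates the imagery an optical bird detector sees in the
field: a flat grayscale background with mild sensor noise, localized
"quivering leaves" flicker patches, small moving bird blobs, coherent
flocks of five or more birds sharing a velocity (with small per-member
jitter), near-camera insects taking large erratic random-walk steps, and
an occasional large slow helicopter blob.  Every frame comes with tight
ground-truth bounding boxes and class labels, so the detector,
classifier, evaluator and trigger can all be exercised end to end
without any recorded footage.

All randomness flows from a single seed: identical configs produce
byte-identical frames and annotations.

Blob sizes follow the qualitative size/distance relations of field
imagery — birds a few pixels across, insects one or two pixels (they fly
close to the lens but are tiny), helicopters 15+ pixels and slow.

:func:`make_fixture_from_counts` serves a different purpose: it lays out
an abstract detection/annotation set on a grid that, when run through
the evaluator at IoU 0.5, reproduces a requested set of per-class
tallies and confusion-matrix cells exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from flockwatch.boxes import BoundingBox, hull_of
from flockwatch.classify import Annotation, Detection, ObjectClass
from flockwatch.evaluation import ClassCounts, ConfusionMatrix
from flockwatch.motion import Frame


@dataclass(frozen=True)
class QuiverPatch:
    """A background region flickering around its base intensity.

    The patch intensity swings by ±amplitude, flipping sign every
    ``period`` frames; with period 1 the per-frame difference signal is
    2*amplitude inside the region.
    """

    region: BoundingBox
    amplitude: float
    period: int = 1

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("quiver amplitude must be nonnegative")
        if self.period < 1:
            raise ValueError("quiver period must be >= 1")

    def offset(self, frame_index: int) -> float:
        return self.amplitude if (frame_index // self.period) % 2 == 0 else -self.amplitude


@dataclass(frozen=True)
class ObjectSpec:
    """One moving object (or flock of objects) planted in the scene.

    ``start`` is the initial blob center (x, y); positions propagate
    linearly at ``velocity`` px/frame.  Flocks place ``member_count``
    birds on a fixed formation of pitch ``spacing`` around the moving
    centroid, each with per-frame positional jitter of ``jitter`` px.
    Bugs additionally take random-walk steps of scale ``walk_step``.
    """

    kind: ObjectClass
    start: tuple[float, float]
    velocity: tuple[float, float] = (0.0, 0.0)
    size: int = 3
    intensity: int = 255
    member_count: int = 6
    spacing: float = 9.0
    jitter: float = 0.5
    walk_step: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ObjectClass(self.kind))
        if self.size < 1:
            raise ValueError("blob size must be >= 1")
        if not 0 <= self.intensity <= 255:
            raise ValueError("intensity must lie in [0, 255]")
        if self.kind is ObjectClass.FLOCK and self.member_count < 5:
            raise ValueError(
                f"a flock has at least five members, got {self.member_count}"
            )


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic scene; the seed fixes everything."""

    width: int = 160
    height: int = 120
    n_frames: int = 20
    seed: int = 0
    background_level: int = 120
    noise_sigma: float = 2.0
    drop_offscreen: bool = False  # True: drop clipped objects' annotations
    quiver: tuple[QuiverPatch, ...] = ()
    objects: tuple[ObjectSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1 or self.n_frames < 1:
            raise ValueError("scene dimensions and frame count must be positive")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must lie in [0, 255]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        object.__setattr__(self, "quiver", tuple(self.quiver))
        object.__setattr__(self, "objects", tuple(self.objects))
        for spec in self.objects:
            x, y = spec.start
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"object start {spec.start} lies outside the frame")


def _formation_offsets(count: int, spacing: float) -> list[tuple[float, float]]:
    """Two staggered rows — the compact V-ish pattern of a small flock."""
    out = []
    per_row = (count + 1) // 2
    for i in range(count):
        row, col = divmod(i, per_row)
        out.append((col * spacing + row * spacing / 2.0, row * spacing * 0.8))
    return out


def _blob_box(cx: float, cy: float, size: int, width: int, height: int) -> BoundingBox | None:
    """Clipped pixel box of a size x size blob centered at (cx, cy)."""
    x0 = int(round(cx)) - size // 2
    y0 = int(round(cy)) - size // 2
    cx0, cy0 = max(x0, 0), max(y0, 0)
    cx1, cy1 = min(x0 + size, width), min(y0 + size, height)
    if cx1 <= cx0 or cy1 <= cy0:
        return None
    return BoundingBox(cx0, cy0, cx1, cy1)


def generate_scene(config: SceneConfig) -> tuple[list[Frame], list[list[Annotation]]]:
    """Render the scene: one Frame and one annotation list per time step."""
    rng = np.random.default_rng(config.seed)
    frames: list[Frame] = []
    annotations: list[list[Annotation]] = []
    # Bug random walks accumulate; draw displacement increments in a fixed
    # object order each frame so the seed fully determines the output.
    walk: dict[int, np.ndarray] = {
        i: np.zeros(2) for i, s in enumerate(config.objects) if s.kind is ObjectClass.BUG
    }

    for t in range(config.n_frames):
        canvas = np.full(
            (config.height, config.width), float(config.background_level), dtype=np.float64
        )
        for patch in config.quiver:
            r = patch.region
            canvas[r.y0 : r.y1, r.x0 : r.x1] += patch.offset(t)

        frame_anns: list[Annotation] = []
        for i, spec in enumerate(config.objects):
            cx = spec.start[0] + spec.velocity[0] * t
            cy = spec.start[1] + spec.velocity[1] * t
            if spec.kind is ObjectClass.BUG:
                if t > 0:
                    walk[i] = walk[i] + rng.normal(0.0, spec.walk_step, size=2)
                cx, cy = cx + walk[i][0], cy + walk[i][1]

            if spec.kind is ObjectClass.FLOCK:
                member_boxes = []
                for ox, oy in _formation_offsets(spec.member_count, spec.spacing):
                    jx, jy = rng.normal(0.0, spec.jitter, size=2)
                    box = _blob_box(
                        cx + ox + jx, cy + oy + jy, spec.size, config.width, config.height
                    )
                    if box is not None:
                        canvas[box.y0 : box.y1, box.x0 : box.x1] = spec.intensity
                        member_boxes.append(box)
                if member_boxes and not (config.drop_offscreen and len(member_boxes) < spec.member_count):
                    frame_anns.append(
                        Annotation(box=hull_of(member_boxes), label=ObjectClass.FLOCK)
                    )
            else:
                box = _blob_box(cx, cy, spec.size, config.width, config.height)
                clipped = box is not None and box.area < spec.size * spec.size
                if box is not None:
                    canvas[box.y0 : box.y1, box.x0 : box.x1] = spec.intensity
                    if not (config.drop_offscreen and clipped):
                        frame_anns.append(Annotation(box=box, label=spec.kind))

        if config.noise_sigma > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sigma, size=canvas.shape)
        frames.append(Frame(pixels=np.clip(np.rint(canvas), 0, 255).astype(np.uint8), index=t))
        annotations.append(frame_anns)
    return frames, annotations


def benign_reference_scene(seed: int = 0) -> SceneConfig:
    """The standard high-contrast test scene: 20 frames, three flocks.

    Flock trajectories are laid out so the three formations stay well
    separated for the whole sequence; contrast is high enough that every
    member clears the default motion threshold.  Used as the benign
    end-to-end self-consistency benchmark.
    """
    mk = lambda start, vel: ObjectSpec(
        kind=ObjectClass.FLOCK,
        start=start,
        velocity=vel,
        size=3,
        intensity=230,
        member_count=6,
        spacing=9.0,
        jitter=0.4,
    )
    return SceneConfig(
        width=240,
        height=160,
        n_frames=20,
        seed=seed,
        background_level=60,
        noise_sigma=2.0,
        objects=(
            mk((40.0, 30.0), (2.0, 1.0)),
            mk((170.0, 100.0), (-2.0, -1.0)),
            mk((40.0, 110.0), (2.0, -1.0)),
        ),
    )


def make_fixture_from_counts(
    counts: dict[ObjectClass, ClassCounts], confusion: ConfusionMatrix
) -> tuple[list[Detection], list[Annotation]]:
    """Abstract detection/annotation set realizing given tallies exactly.

    Places disjoint unit boxes on a grid: one coincident
    detection/annotation pair per confusion-matrix cell entry, a lone
    annotation per undetected ground-truth object, and a lone detection
    per out-of-class false positive.  Matching at IoU 0.5 then
    reproduces ``counts`` and ``confusion`` verbatim.

    Raises ValueError if the requested numbers are internally
    inconsistent (diagonal != TP, or FP not accounted for by cross-class
    cells plus out-of-class detections).
    """
    for c, cc in counts.items():
        diag = confusion.cell(c, c)
        if diag != cc.tp:
            raise ValueError(
                f"inconsistent fixture request for {c.value}: confusion diagonal "
                f"{diag} != tp {cc.tp}"
            )
        cross_fp = sum(confusion.cell(g, c) for g in counts if g is not c)
        out_fp = confusion.out_of_class_fp.get(c, 0)
        if cross_fp + out_fp != cc.fp:
            raise ValueError(
                f"inconsistent fixture request for {c.value}: fp {cc.fp} != "
                f"{cross_fp} cross-class + {out_fp} out-of-class"
            )
        row = sum(confusion.cell(c, p) for p in counts)
        if row > cc.gt:
            raise ValueError(
                f"inconsistent fixture request for {c.value}: matched row sum {row} "
                f"exceeds gt {cc.gt}"
            )

    detections: list[Detection] = []
    annotations: list[Annotation] = []
    cell_idx = 0

    def next_box() -> BoundingBox:
        nonlocal cell_idx
        x, y = 3 * (cell_idx % 1000), 3 * (cell_idx // 1000)
        cell_idx += 1
        return BoundingBox(x, y, x + 1, y + 1)

    def next_conf() -> float:
        return 0.9 - 1e-4 * len(detections)

    classes = list(counts)
    for g in classes:  # matched pairs, coincident boxes (IoU 1.0)
        for p in classes:
            for _ in range(confusion.cell(g, p)):
                box = next_box()
                annotations.append(Annotation(box=box, label=g))
                detections.append(Detection(box=box, label=p, confidence=next_conf()))
    for g in classes:  # ground truth nothing ever matched
        unmatched = counts[g].gt - sum(confusion.cell(g, p) for p in classes)
        for _ in range(unmatched):
            annotations.append(Annotation(box=next_box(), label=g))
    for p in classes:  # detections matching no annotation at all
        for _ in range(confusion.out_of_class_fp.get(p, 0)):
            detections.append(Detection(box=next_box(), label=p, confidence=next_conf()))
    return detections, annotations
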