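"""Flock-only actuation policy.

The scaring actuator (loudspeaker, gas cannon, laser) is fired only when
a *flock* is detected with sufficient confidence — never for an
individual bird, however confident the classifier is.  The confidence
threshold defaults to 30%, inclusive.  Optional multi-frame confirmation
requires the flock to persist over consecutive frames before firing, and
an optional cooldown enforces a minimum spacing between events to model
actuator duty limits.  Both options default off, which reproduces the
basic fire-on-sight behaviour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from flockwatch.boxes import BoundingBox
from flockwatch.classify import Detection, ObjectClass


@dataclass(frozen=True)
class TriggerPolicy:
    """Actuation rule parameters.

    confidence_threshold
        Minimum flock confidence (inclusive) that can fire, in [0, 1].
    confirm_frames
        Number of consecutive frames a qualifying flock must be present
        before an event is emitted (1 = fire immediately).
    cooldown_frames
        Minimum number of frames between consecutive events (0 = none);
        events are at least cooldown_frames + 1 frames apart.
    """

    confidence_threshold: float = 0.30
    confirm_frames: int = 1
    cooldown_frames: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError(
                f"confidence_threshold must lie in [0, 1], got {self.confidence_threshold}"
            )
        if self.confirm_frames < 1:
            raise ValueError(f"confirm_frames must be >= 1, got {self.confirm_frames}")
        if self.cooldown_frames < 0:
            raise ValueError(f"cooldown_frames must be >= 0, got {self.cooldown_frames}")


@dataclass(frozen=True)
class TriggerEvent:
    """Record that the scaring actuator would be switched at a frame."""

    frame_index: int
    flock_box: BoundingBox
    confidence: float


@dataclass
class FlockTrigger:
    """Stateful trigger: feed per-frame detections, collect events."""

    policy: TriggerPolicy = field(default_factory=TriggerPolicy)
    _streak: int = field(default=0, init=False)
    _last_event_frame: int | None = field(default=None, init=False)

    def update(self, frame_index: int, detections: Sequence[Detection]) -> list[TriggerEvent]:
        """Process one frame's detections; returns the events emitted (0 or 1).

        A qualifying detection is one labeled flock with confidence at
        or above the policy threshold.  The confirmation streak counts
        consecutive frames with at least one qualifying flock; it resets
        on any frame without one.
        """
        qualifying = [
            d
            for d in detections
            if d.label is ObjectClass.FLOCK
            and d.confidence >= self.policy.confidence_threshold
        ]
        if not qualifying:
            self._streak = 0
            return []
        self._streak += 1
        if self._streak < self.policy.confirm_frames:
            return []
        if (
            self._last_event_frame is not None
            and frame_index - self._last_event_frame <= self.policy.cooldown_frames
        ):
            return []
        best = max(qualifying, key=lambda d: d.confidence)
        self._last_event_frame = frame_index
        return [
            TriggerEvent(frame_index=frame_index, flock_box=best.box, confidence=best.confidence)
        ]

    def run(self, per_frame_detections: Sequence[Sequence[Detection]]) -> list[TriggerEvent]:
        """Run a whole stream (frame indices 0..n-1); returns all events."""
        events: list[TriggerEvent] = []
        for i, dets in enumerate(per_frame_detections):
            events.extend(self.update(i, dets))
        return events

    def reset(self) -> None:
        self._streak = 0
        self._last_event_frame = None


def write_event_log(events: Iterable[TriggerEvent], path: str | Path) -> None:
    """Append trigger events to a JSON-lines log."""
    with open(path, "a") as fh:
        for e in events:
            fh.write(
                json.dumps(
                    {"frame": e.frame_index, "box": e.flock_box.as_list(), "confidence": e.confidence}
                )
                + "\n"
            )
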