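"""Axis-aligned pixel bounding boxes.

Coordinates are 0-based and half-open: a box covers the pixel set
``[x0, x1) x [y0, y1)``, so ``area == (x1 - x0) * (y1 - y0)`` and two
boxes sharing only an edge do not intersect.  This convention is used
everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BoundingBox:
    """A non-empty axis-aligned pixel rectangle ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(
                f"degenerate box: need x1 > x0 and y1 > y0, got "
                f"({self.x0}, {self.y0}, {self.x1}, {self.y1})"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def intersection_area(self, other: "BoundingBox") -> int:
        w = min(self.x1, other.x1) - max(self.x0, other.x0)
        h = min(self.y1, other.y1) - max(self.y0, other.y0)
        return w * h if (w > 0 and h > 0) else 0

    def union_area(self, other: "BoundingBox") -> int:
        return self.area + other.area - self.intersection_area(other)

    def hull(self, other: "BoundingBox") -> "BoundingBox":
        """Smallest box containing both operands."""
        return BoundingBox(
            min(self.x0, other.x0),
            min(self.y0, other.y0),
            max(self.x1, other.x1),
            max(self.y1, other.y1),
        )

    def contains_box(self, other: "BoundingBox") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and self.x1 >= other.x1
            and self.y1 >= other.y1
        )

    def as_list(self) -> list[int]:
        return [self.x0, self.y0, self.x1, self.y1]

    @classmethod
    def from_sequence(cls, seq) -> "BoundingBox":
        x0, y0, x1, y1 = (int(v) for v in seq)
        return cls(x0, y0, x1, y1)


def hull_of(boxes) -> BoundingBox:
    """Smallest box containing every box in a non-empty iterable."""
    boxes = list(boxes)
    if not boxes:
        raise ValueError("hull of an empty box collection is undefined")
    out = boxes[0]
    for b in boxes[1:]:
        out = out.hull(b)
    return out
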