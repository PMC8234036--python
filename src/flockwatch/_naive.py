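"""Pure-Python per-pixel reference implementation of the motion pipeline.

Everything here is written with explicit double loops and a hand-rolled
flood fill — no numpy vectorisation, no scipy labeling — so it can serve
as an independent cross-check of the vectorised detector in
:mod:`flockwatch.motion`.  It is deliberately slow and only intended for
small images.
"""

from __future__ import annotations

from flockwatch.boxes import BoundingBox


def naive_difference(current: list[list[int]], previous: list[list[int]]) -> list[list[int]]:
    h, w = len(current), len(current[0])
    return [[abs(current[y][x] - previous[y][x]) for x in range(w)] for y in range(h)]


def naive_threshold(diff: list[list[float]], threshold: float) -> list[list[int]]:
    return [[1 if v > threshold else 0 for v in row] for row in diff]


def naive_update_accumulator(
    acc: list[list[float]], diff: list[list[int]], rate: float
) -> list[list[float]]:
    h, w = len(acc), len(acc[0])
    return [[(1.0 - rate) * acc[y][x] + rate * diff[y][x] for x in range(w)] for y in range(h)]


def naive_subtract(diff: list[list[int]], acc: list[list[float]]) -> list[list[float]]:
    h, w = len(diff), len(diff[0])
    out = []
    for y in range(h):
        row = []
        for x in range(w):
            v = diff[y][x] - acc[y][x]
            row.append(v if v > 0 else 0.0)
        out.append(row)
    return out


def naive_extract(mask: list[list[int]], min_area: int) -> list[BoundingBox]:
    """Flood-fill connected components (8-connectivity), tight boxes."""
    h, w = len(mask), len(mask[0])
    seen = [[False] * w for _ in range(h)]
    boxes = []
    for y in range(h):
        for x in range(w):
            if mask[y][x] and not seen[y][x]:
                stack = [(y, x)]
                seen[y][x] = True
                pixels = []
                while stack:
                    cy, cx = stack.pop()
                    pixels.append((cy, cx))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = cy + dy, cx + dx
                            if 0 <= ny < h and 0 <= nx < w and mask[ny][nx] and not seen[ny][nx]:
                                seen[ny][nx] = True
                                stack.append((ny, nx))
                if len(pixels) >= min_area:
                    ys = [p[0] for p in pixels]
                    xs = [p[1] for p in pixels]
                    boxes.append(
                        BoundingBox(x0=min(xs), y0=min(ys), x1=max(xs) + 1, y1=max(ys) + 1)
                    )
    boxes.sort(key=lambda b: (b.y0, b.x0))
    return boxes


def naive_pipeline(
    frames: list[list[list[int]]],
    threshold: float,
    rate: float,
    min_area: int,
) -> list[list[BoundingBox]]:
    """Full detector on a sequence of 2-D intensity lists.

    Mirrors the order used by :class:`flockwatch.motion.MotionDetector`:
    difference, accumulate, subtract, threshold, extract; frame 0 emits
    nothing.  The uint8 quantisation of the vectorised path is
    reproduced by truncating the filtered difference to ints.
    """
    if not frames:
        return []
    h, w = len(frames[0]), len(frames[0][0])
    acc = [[0.0] * w for _ in range(h)]
    prev = frames[0]
    out: list[list[BoundingBox]] = [[]]
    for cur in frames[1:]:
        diff = naive_difference(cur, prev)
        acc = naive_update_accumulator(acc, diff, rate)
        filtered = naive_subtract(diff, acc)
        quantised = [[int(v) for v in row] for row in filtered]
        mask = naive_threshold(quantised, threshold)
        out.append(naive_extract(mask, min_area))
        prev = cur
    return out
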