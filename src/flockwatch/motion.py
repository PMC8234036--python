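"""Differential moving-object detector with accumulated-background filtering.

The detector follows the classic frame-differencing scheme used by
low-power field cameras watching for birds: the absolute difference of
consecutive grayscale frames marks everything that moved, a running
*accumulated differential image* of the background is subtracted from it
to suppress persistent low-level motion (quivering grapevine leaves,
waving vegetation), the filtered difference is thresholded to a binary
mask, and connected components of the mask become candidate object
bounding boxes.

The accumulated background is an exponential moving average of past
differential images with rate ``alpha``: a patch that flickers every
frame accumulates until its own difference signal is cancelled, while a
bird crossing the scene keeps hitting fresh pixels and stays visible.

Pipeline order per frame (``MotionDetector.process``)::

    diff   = |current - previous|
    acc    = (1 - alpha) * acc + alpha * diff
    filt   = max(diff - acc, 0)
    mask   = filt > threshold
    boxes  = connected components of mask with >= min_area pixels

Frame 0 initialises the state and emits no detections (there is no
previous frame to difference against).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from flockwatch.boxes import BoundingBox

#: 8-connectivity structuring element: small distant birds often leave
#: diagonal-touching pixel pairs that must count as one object.
_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Frame:
    """One grayscale image in a timestamped sequence.

    ``pixels`` is a 2-D uint8 array (intensities 0..255); ``index`` is
    the frame's position in its sequence.
    """

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"frame pixels must be a non-empty 2-D array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if np.any(px < 0) or np.any(px > 255):
                raise ValueError("frame intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.index < 0:
            raise ValueError(f"frame index must be nonnegative, got {self.index}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, 3|4]) image to 8-bit grayscale.

    Color frames are converted with the ITU-R 601 luma weights before
    differencing; the motion signal is intensity-based.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        gray = rgb @ np.array([0.299, 0.587, 0.114])
    else:
        raise ValueError(f"cannot interpret array of shape {arr.shape} as an image")
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class BackgroundAccumulator:
    """Running accumulated differential image of the background.

    ``values`` holds the exponential moving average of past differential
    images; ``rate`` (alpha in [0, 1]) is the per-frame accumulation
    weight.  rate=0 freezes the accumulator, rate=1 replaces it with the
    latest difference.
    """

    values: np.ndarray
    rate: float = 0.05
    frames_seen: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise ValueError(f"accumulator values must be 2-D, got shape {vals.shape}")
        if np.any(vals < 0):
            raise ValueError("accumulator values must be nonnegative")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"accumulation rate must lie in [0, 1], got {self.rate}")
        object.__setattr__(self, "values", vals)

    @classmethod
    def zeros(cls, shape: tuple[int, int], rate: float = 0.05) -> "BackgroundAccumulator":
        return cls(values=np.zeros(shape, dtype=np.float64), rate=rate)


def difference_frames(current: Frame, previous: Frame) -> Frame:
    """Per-pixel absolute difference of two frames (commutative)."""
    if current.shape != previous.shape:
        raise ValueError(
            f"frame dimension mismatch: current {current.shape} vs previous {previous.shape}"
        )
    diff = np.abs(current.pixels.astype(np.int16) - previous.pixels.astype(np.int16))
    return Frame(pixels=diff.astype(np.uint8), index=current.index)


def threshold_binary(diff: Frame, threshold: float) -> np.ndarray:
    """Binarise a differential image: bit = 1 iff pixel > threshold.

    Returns a 2-D uint8 array of {0, 1} with the frame's shape.  The set
    bit count is non-increasing in the threshold.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    return (diff.pixels > threshold).astype(np.uint8)


def update_accumulator(acc: BackgroundAccumulator, diff: Frame) -> BackgroundAccumulator:
    """Fold a differential image into the accumulated background.

    Exponential moving average: ``new = (1 - rate) * old + rate * diff``.
    """
    if acc.values.shape != diff.shape:
        raise ValueError(
            f"dimension mismatch: accumulator {acc.values.shape} vs diff {diff.shape}"
        )
    new_vals = (1.0 - acc.rate) * acc.values + acc.rate * diff.pixels.astype(np.float64)
    return replace(acc, values=new_vals, frames_seen=acc.frames_seen + 1)


def subtract_background(diff: Frame, acc: BackgroundAccumulator) -> Frame:
    """Remove the accumulated background from a differential image.

    Clamps at zero: negative evidence carries no information for a
    binary motion detector.
    """
    if acc.values.shape != diff.shape:
        raise ValueError(
            f"dimension mismatch: diff {diff.shape} vs accumulator {acc.values.shape}"
        )
    filtered = np.clip(diff.pixels.astype(np.float64) - acc.values, 0, 255)
    return Frame(pixels=filtered.astype(np.uint8), index=diff.index)


def extract_objects(mask: np.ndarray, min_area: int = 1) -> list[BoundingBox]:
    """Tight bounding boxes of the 8-connected components of a binary mask.

    Components with fewer than ``min_area`` pixels are discarded; output
    is sorted by (y0, x0) so detection logs are reproducible.
    """
    if min_area < 1:
        raise ValueError(f"min_area must be >= 1, got {min_area}")
    mask = np.asarray(mask)
    labels, n = ndimage.label(mask > 0, structure=_EIGHT_CONNECTED)
    if n == 0:
        return []
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    boxes = []
    for lab, slc in enumerate(ndimage.find_objects(labels), start=1):
        if slc is None or areas[lab - 1] < min_area:
            continue
        ys, xs = slc
        boxes.append(BoundingBox(x0=xs.start, y0=ys.start, x1=xs.stop, y1=ys.stop))
    boxes.sort(key=lambda b: (b.y0, b.x0))
    return boxes


@dataclass(frozen=True)
class MotionConfig:
    """Tunables of the differential detector.

    threshold
        Binarisation level on the filtered differential image (0..255).
    accumulator_rate
        EMA rate alpha of the accumulated background.
    min_area
        Minimum connected-component pixel count kept as an object.
    """

    threshold: float = 25.0
    accumulator_rate: float = 0.05
    min_area: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must lie in [0, 255], got {self.threshold}")
        if not 0.0 <= self.accumulator_rate <= 1.0:
            raise ValueError(f"accumulator_rate must lie in [0, 1], got {self.accumulator_rate}")
        if self.min_area < 1:
            raise ValueError(f"min_area must be >= 1, got {self.min_area}")


@dataclass
class MotionDetector:
    """Stateful per-frame motion detector (difference → accumulate →
    background-subtract → threshold → extract).

    Feed frames in order with :meth:`process`; each call returns the
    surviving object boxes and a flag saying whether the frame contains
    a positive detection and should be stored.
    """

    config: MotionConfig = field(default_factory=MotionConfig)
    _previous: Frame | None = field(default=None, init=False, repr=False)
    _accumulator: BackgroundAccumulator | None = field(default=None, init=False, repr=False)

    @property
    def accumulator(self) -> BackgroundAccumulator | None:
        return self._accumulator

    def process(self, frame: Frame) -> tuple[list[BoundingBox], bool]:
        """Run one frame through the pipeline.

        Returns ``(boxes, store_flag)``; ``store_flag`` is true iff at
        least one box survives.  The first frame only initialises the
        state and never yields detections.
        """
        if self._previous is None:
            self._previous = frame
            self._accumulator = BackgroundAccumulator.zeros(
                frame.shape, rate=self.config.accumulator_rate
            )
            return [], False
        diff = difference_frames(frame, self._previous)
        self._accumulator = update_accumulator(self._accumulator, diff)
        filtered = subtract_background(diff, self._accumulator)
        mask = threshold_binary(filtered, self.config.threshold)
        boxes = extract_objects(mask, self.config.min_area)
        self._previous = frame
        return boxes, bool(boxes)

    def reset(self) -> None:
        self._previous = None
        self._accumulator = None


def detect_sequence(
    frames: list[Frame], config: MotionConfig | None = None
) -> list[list[BoundingBox]]:
    """Convenience: run a whole frame sequence, one box list per frame."""
    det = MotionDetector(config=config or MotionConfig())
    return [det.process(f)[0] for f in frames]
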