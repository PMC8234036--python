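"""Frame-sequence and detection-log input/output.

Frame sequences are directories of lexicographically ordered PNG or PGM
files.  Detections are logged one frame per line as JSON:
``{"frame": int, "boxes": [[x0, y0, x1, y1], ...]}``.  Frames containing
at least one positive detection can be stored to an output directory
(the local stand-in for the deployed system's cloud upload).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import yaml

from flockwatch.boxes import BoundingBox
from flockwatch.motion import Frame, MotionConfig, to_grayscale

FRAME_SUFFIXES = (".png", ".pgm")


def read_frame_dir(path: str | Path) -> list[Frame]:
    """Load a directory of PNG/PGM files as a frame sequence.

    Files are ordered lexicographically by name; color images are
    converted to 8-bit grayscale.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in FRAME_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no {'/'.join(FRAME_SUFFIXES)} frames found in {path}")
    frames = [Frame(pixels=to_grayscale(iio.imread(p)), index=i) for i, p in enumerate(files)]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"frames in one sequence must share dimensions, got {sorted(shapes)}")
    return frames


def write_frame_dir(frames: Sequence[Frame], path: str | Path, prefix: str = "frame") -> None:
    """Write frames as zero-padded PNG files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for f in frames:
        iio.imwrite(path / f"{prefix}_{f.index:05d}.png", f.pixels)


def store_frame(frame: Frame, store_dir: str | Path) -> Path:
    """Store one positively detected frame to the output directory."""
    store_dir = Path(store_dir)
    store_dir.mkdir(parents=True, exist_ok=True)
    out = store_dir / f"frame_{frame.index:05d}.png"
    iio.imwrite(out, frame.pixels)
    return out


def write_detection_log(
    per_frame_boxes: Iterable[tuple[int, Sequence[BoundingBox]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for frame_index, boxes in per_frame_boxes:
            fh.write(
                json.dumps({"frame": frame_index, "boxes": [b.as_list() for b in boxes]}) + "\n"
            )


def read_detection_log(path: str | Path) -> list[tuple[int, list[BoundingBox]]]:
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            out.append((rec["frame"], [BoundingBox.from_sequence(b) for b in rec["boxes"]]))
    return out


def load_motion_config(path: str | Path) -> tuple[MotionConfig, Path | None]:
    """Read a YAML config (keys: threshold, accumulator_rate, min_area,
    store_dir); returns the config and the optional store directory."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"threshold", "accumulator_rate", "min_area", "store_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; expected {sorted(known)}")
    store = raw.pop("store_dir", None)
    return MotionConfig(**raw), (Path(store) if store else None)
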