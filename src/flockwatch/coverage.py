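"""Camera-coverage planning for 360° vineyard surveillance.

Each optical detector watches a circular sector defined by its horizontal
field of view (FOV) and its detection range — flocks are reliably
captured up to about 300 m, beyond which false negatives appear.  Full
panoramic coverage from one mast therefore needs 360/FOV cameras; the
fractional value is reported to one decimal alongside a nearest-integer
recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

_EPS = 1e-9  # float slack at inclusive sector edges


@dataclass(frozen=True)
class CameraSpec:
    """A camera's horizontal field of view (degrees) and range (meters)."""

    horizontal_fov: float
    range_m: float = 300.0

    def __post_init__(self) -> None:
        if not 0.0 < self.horizontal_fov <= 360.0:
            raise ValueError(
                f"horizontal_fov must lie in (0, 360], got {self.horizontal_fov}"
            )
        if self.range_m <= 0:
            raise ValueError(f"range must be positive, got {self.range_m}")


def detectors_for_full_circle(spec: CameraSpec) -> float:
    """Cameras needed for 360° coverage: 360/FOV, one decimal (half-up)."""
    frac = Decimal(360) / Decimal(str(spec.horizontal_fov))
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def recommended_detectors(spec: CameraSpec) -> int:
    """Nearest-integer camera count for 360° coverage."""
    frac = Decimal(360) / Decimal(str(spec.horizontal_fov))
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def sector_covers(
    spec: CameraSpec,
    camera_bearing: float,
    target_bearing: float,
    target_distance: float,
) -> bool:
    """Whether a target lies inside the camera's sector.

    True iff the wrapped angular offset between target and camera
    bearing is at most FOV/2 (inclusive) and the distance is at most the
    camera range (inclusive: a flock at exactly 300 m is covered).
    """
    if not (0.0 <= camera_bearing < 360.0 and 0.0 <= target_bearing < 360.0):
        raise ValueError("bearings must lie in [0, 360)")
    if target_distance < 0:
        raise ValueError(f"distance must be nonnegative, got {target_distance}")
    offset = abs(target_bearing - camera_bearing) % 360.0
    offset = min(offset, 360.0 - offset)
    return offset <= spec.horizontal_fov / 2.0 + _EPS and target_distance <= spec.range_m
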