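"""Screen geometry: pixel <-> visual-angle conversions.

All conversions use the full-angle formula ``angle = 2*atan(span / (2*distance))``
rather than the small-angle approximation; the two differ by a few hundredths of a
degree at the extents of a desktop monitor, which matters when a single pixel pitch
must reproduce both a 0.66 deg calibration dot and a 3.3 deg inter-stimulus span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidArgumentError

#: Default experimental screen: 1366 x 768 px at 60 cm viewing distance.
DEFAULT_WIDTH_PX = 1366
DEFAULT_HEIGHT_PX = 768
DEFAULT_DISTANCE_MM = 600.0

#: Pitch anchored on a 20 px target subtending 0.657 deg at 600 mm (~0.344 mm/px).
DEFAULT_PITCH_MM = 2 * DEFAULT_DISTANCE_MM * math.tan(math.radians(0.657) / 2) / 20.0


def derive_pixel_pitch(anchor_px: float, anchor_deg: float, distance_mm: float) -> float:
    """Solve for the pixel pitch (mm/px) from one known pixel-span/visual-angle pair.

    Inverts ``anchor_deg = 2*atan(anchor_px * pitch / (2 * distance_mm))``.

    Parameters
    ----------
    anchor_px : pixel extent of the anchor feature (> 0).
    anchor_deg : visual angle it subtends, degrees, in (0, 180).
    distance_mm : viewing distance (> 0).
    """
    if anchor_px <= 0 or distance_mm <= 0:
        raise InvalidArgumentError("anchor_px and distance_mm must be positive")
    if not 0 < anchor_deg < 180:
        raise InvalidArgumentError("anchor_deg must lie in (0, 180) degrees")
    return 2.0 * distance_mm * math.tan(math.radians(anchor_deg) / 2.0) / anchor_px


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical description of the stimulus screen.

    Attributes
    ----------
    width_px, height_px : screen resolution (integers, strictly positive).
    viewing_distance_mm : eye-to-screen distance.
    pixel_pitch_mm : physical size of one pixel.
    """

    width_px: int = DEFAULT_WIDTH_PX
    height_px: int = DEFAULT_HEIGHT_PX
    viewing_distance_mm: float = DEFAULT_DISTANCE_MM
    pixel_pitch_mm: float = field(default=DEFAULT_PITCH_MM)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidArgumentError("screen resolution must be positive")
        if int(self.width_px) != self.width_px or int(self.height_px) != self.height_px:
            raise InvalidArgumentError("screen resolution must be integral")
        if self.viewing_distance_mm <= 0 or self.pixel_pitch_mm <= 0:
            raise InvalidArgumentError("distance and pixel pitch must be positive")

    @classmethod
    def from_anchor(
        cls,
        anchor_px: float,
        anchor_deg: float,
        *,
        width_px: int = DEFAULT_WIDTH_PX,
        height_px: int = DEFAULT_HEIGHT_PX,
        distance_mm: float = DEFAULT_DISTANCE_MM,
    ) -> "ScreenGeometry":
        """Build a geometry whose pitch is derived from a known span/angle pair."""
        pitch = derive_pixel_pitch(anchor_px, anchor_deg, distance_mm)
        return cls(width_px, height_px, distance_mm, pitch)

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


def px_to_deg(length_px: float, geom: ScreenGeometry) -> float:
    """Visual angle (degrees) subtended by ``length_px`` pixels at the viewer."""
    if length_px < 0:
        raise InvalidArgumentError("length_px must be non-negative")
    span_mm = length_px * geom.pixel_pitch_mm
    return math.degrees(2.0 * math.atan(span_mm / (2.0 * geom.viewing_distance_mm)))


def deg_to_px(angle_deg: float, geom: ScreenGeometry) -> float:
    """Pixel extent subtending ``angle_deg`` degrees; exact inverse of px_to_deg."""
    if not 0 <= angle_deg < 180:
        raise InvalidArgumentError("angle_deg must lie in [0, 180) degrees")
    span_mm = 2.0 * geom.viewing_distance_mm * math.tan(math.radians(angle_deg) / 2.0)
    return span_mm / geom.pixel_pitch_mm
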