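"""Pixel/physical-unit calibration.

Two routes to a :class:`Scale` are supported: scanner resolution in dots
per inch (``pixels_per_cm = dpi / 2.54``), or a two-point measurement on a
scanned ruler (``pixel_size = known_length / euclidean_distance(p1, p2)``).
All physical quantities downstream are expressed in cm / cm**2 / cm**3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from .errors import DegenerateCalibrationError, InvalidArgumentError

CM_PER_INCH = 2.54

__all__ = ["Scale", "scale_from_dpi", "scale_from_ruler", "CM_PER_INCH"]


@dataclass(frozen=True)
class Scale:
    """Isotropic pixel calibration.

    Attributes
    ----------
    pixel_size:
        Physical edge length of one pixel, in cm.
    pixels_per_cm:
        Number of pixels spanning 1 cm; reciprocal of ``pixel_size``.
    source:
        Which calibration route produced this scale.
    """

    pixel_size: float
    pixels_per_cm: float
    source: Literal["dpi", "ruler", "manual"] = "manual"

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0 and math.isfinite(self.pixel_size)):
            raise InvalidArgumentError(f"pixel_size must be positive, got {self.pixel_size}")
        if abs(self.pixel_size * self.pixels_per_cm - 1.0) > 1e-12:
            raise InvalidArgumentError(
                "pixel_size and pixels_per_cm must be reciprocal "
                f"(product {self.pixel_size * self.pixels_per_cm})"
            )

    @classmethod
    def from_pixel_size(cls, pixel_size: float, source: str = "manual") -> "Scale":
        if pixel_size <= 0:
            raise InvalidArgumentError(f"pixel_size must be positive, got {pixel_size}")
        return cls(pixel_size=pixel_size, pixels_per_cm=1.0 / pixel_size, source=source)

    def to_cm(self, n_pixels: float) -> float:
        """Convert a pixel count (length) to cm."""
        return n_pixels * self.pixel_size

    def to_pixels(self, length_cm: float) -> float:
        """Convert a length in cm to a (fractional) pixel count."""
        return length_cm * self.pixels_per_cm


def scale_from_dpi(dpi: float) -> Scale:
    """Build a :class:`Scale` from a scanner resolution in dots per inch.

    ``pixels_per_cm = dpi / 2.54`` and ``pixel_size = 2.54 / dpi``; e.g. a
    400 dpi scan gives 157.48 pixels per cm and a pixel size of ~0.0063 cm.
    """
    if not (dpi > 0 and math.isfinite(dpi)):
        raise InvalidArgumentError(f"dpi must be positive and finite, got {dpi}")
    return Scale(pixel_size=CM_PER_INCH / dpi, pixels_per_cm=dpi / CM_PER_INCH, source="dpi")


def scale_from_ruler(
    p1: Sequence[float], p2: Sequence[float], known_length: float
) -> Scale:
    """Build a :class:`Scale` from two points a known physical distance apart.

    The pixel distance is the Euclidean distance between the coordinate
    pairs, so the ruler need not be axis-aligned.

    Parameters
    ----------
    p1, p2:
        Pixel coordinates ``(x, y)`` of two marks on a scanned ruler.
    known_length:
        Physical distance between the marks, in cm.
    """
    if known_length <= 0:
        raise InvalidArgumentError(f"known_length must be positive, got {known_length}")
    if len(p1) != 2 or len(p2) != 2:
        raise InvalidArgumentError("calibration points must be coordinate pairs")
    dist = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    if dist == 0:
        raise DegenerateCalibrationError(f"calibration points coincide at {tuple(p1)}")
    pixel_size = known_length / dist
    return Scale(pixel_size=pixel_size, pixels_per_cm=1.0 / pixel_size, source="ruler")
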