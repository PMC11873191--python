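"""Ground-truth phantom generation: wires of known geometry on a light canvas.

Phantoms emulate validation scans of wires with known length and diameter.
A wire is rasterized as a disc-swept stroke: a pixel is foreground iff its
center lies within ``width/2`` of the polyline, giving a deterministic,
analyzable width with no anti-aliasing.  Closed-form cylinder truths
(length, diameter, lateral surface area, volume, projected area) accompany
every wire, so end-to-end trait recovery can be scored without external
reference software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import math

import numpy as np

from .calibration import Scale, scale_from_dpi
from .errors import InvalidArgumentError, InvalidFixtureError
from .segmentation import GrayImage

BACKGROUND = 235
DEFAULT_WIRE_INTENSITY = 20

# Default fixture grid: stroke widths (px) spanning fine-to-coarse roots and
# two wire lengths (px); rendered at the caller's DPI.
DEFAULT_WIDTHS_PX = (5, 9, 15)
DEFAULT_LENGTHS_PX = (200, 600)

__all__ = [
    "WireSpec",
    "PhantomTruth",
    "render_phantom",
    "render_ruler",
    "default_wire_grid",
    "DEFAULT_WIDTHS_PX",
    "DEFAULT_LENGTHS_PX",
]


@dataclass(frozen=True)
class WireSpec:
    """A single wire: polyline path (x, y in pixels), odd stroke width, and
    dark intensity level."""

    path: Tuple[Tuple[float, float], ...]
    width_px: int
    intensity: int = DEFAULT_WIRE_INTENSITY

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise InvalidArgumentError("wire path needs at least 2 points")
        if self.width_px < 1 or self.width_px % 2 == 0:
            raise InvalidArgumentError(f"width_px must be odd positive, got {self.width_px}")
        if not (0 <= self.intensity <= 80):
            raise InvalidArgumentError(f"wire intensity must be in [0, 80], got {self.intensity}")
        object.__setattr__(self, "path", tuple((float(x), float(y)) for x, y in self.path))

    def length_px(self) -> float:
        """Euclidean polyline length in pixels."""
        pts = np.asarray(self.path)
        return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form cylinder ground truth for one wire, in physical units."""

    length_cm: float
    diameter_cm: float
    sa_cm2: float
    volume_cm3: float
    pa_cm2: float

    def __post_init__(self) -> None:
        for name in ("length_cm", "diameter_cm", "sa_cm2", "volume_cm3", "pa_cm2"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if abs(self.sa_cm2 - math.pi * self.diameter_cm * self.length_cm) > 1e-12:
            raise InvalidArgumentError("sa_cm2 inconsistent with pi * d * L")

    @classmethod
    def from_wire(cls, wire: WireSpec, scale: Scale) -> "PhantomTruth":
        L = wire.length_px() * scale.pixel_size
        d = wire.width_px * scale.pixel_size
        return cls(
            length_cm=L,
            diameter_cm=d,
            sa_cm2=math.pi * d * L,
            volume_cm3=math.pi * (d / 2.0) ** 2 * L,
            pa_cm2=d * L,
        )


def _stroke_mask(wire: WireSpec, shape: Tuple[int, int]) -> np.ndarray:
    """Boolean raster of pixels whose centers lie within width/2 of the path."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    xs = xs.astype(np.float64)
    ys = ys.astype(np.float64)
    radius = wire.width_px / 2.0
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(wire.path)
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            dist2 = (xs - x1) ** 2 + (ys - y1) ** 2
        else:
            t = np.clip(((xs - x1) * dx + (ys - y1) * dy) / seg_len2, 0.0, 1.0)
            dist2 = (xs - (x1 + t * dx)) ** 2 + (ys - (y1 + t * dy)) ** 2
        mask |= dist2 <= radius * radius
    return mask


def render_phantom(
    wires: Sequence[WireSpec],
    canvas: Tuple[int, int],
    dpi: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[GrayImage, List[PhantomTruth]]:
    """Render wires onto a light canvas and return the image with its truths.

    Parameters
    ----------
    wires:
        Wire specifications; strokes must not overlap each other or touch
        the canvas edge.
    canvas:
        Output shape as (height, width) in pixels.
    dpi:
        Resolution used both for the image metadata and the truth values.
    noise_sd:
        Standard deviation of additive Gaussian noise (0 disables it).
    seed:
        Noise generator seed; identical seeds give bit-identical images.
    """
    if noise_sd < 0:
        raise InvalidArgumentError(f"noise_sd must be >= 0, got {noise_sd}")
    scale = scale_from_dpi(dpi)
    img = np.full(canvas, BACKGROUND, dtype=np.float64)
    occupied = np.zeros(canvas, dtype=bool)
    truths: List[PhantomTruth] = []
    for i, wire in enumerate(wires):
        stroke = _stroke_mask(wire, canvas)
        if not stroke.any():
            raise InvalidFixtureError(f"wire {i} renders no pixels on canvas {canvas}")
        if (
            stroke[0, :].any() or stroke[-1, :].any()
            or stroke[:, 0].any() or stroke[:, -1].any()
        ):
            raise InvalidFixtureError(f"wire {i} touches the canvas edge")
        if (stroke & occupied).any():
            raise InvalidFixtureError(f"wire {i} overlaps a previously placed wire")
        occupied |= stroke
        img[stroke] = wire.intensity
        truths.append(PhantomTruth.from_wire(wire, scale))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=canvas)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayImage(img, dpi=dpi), truths


def render_ruler(dpi: float, length_cm: int = 10) -> GrayImage:
    """Render a synthetic scanned ruler with tick marks at 1 cm intervals.

    Tick k sits at column ``margin + round(k * dpi / 2.54)`` — positions are
    rounded, not spacings, so consecutive gaps alternate between floor and
    ceil of the true pixels-per-cm (e.g. 157/158 px at 400 dpi).
    """
    if dpi <= 0:
        raise InvalidArgumentError(f"dpi must be positive, got {dpi}")
    if length_cm < 1:
        raise InvalidArgumentError(f"length_cm must be >= 1, got {length_cm}")
    px_per_cm = dpi / 2.54
    margin = 20
    height = 120
    width = margin * 2 + int(round(length_cm * px_per_cm)) + 1
    img = np.full((height, width), BACKGROUND, dtype=np.uint8)
    for k in range(length_cm + 1):
        x = margin + int(round(k * px_per_cm))
        tick_h = 80 if k % 5 == 0 else 50
        img[height - tick_h :, x] = 0
    img[height - 10 :, margin : margin + int(round(length_cm * px_per_cm)) + 1] = 0
    return GrayImage(img, dpi=dpi)


def default_wire_grid(
    widths_px: Sequence[int] = DEFAULT_WIDTHS_PX,
    lengths_px: Sequence[int] = DEFAULT_LENGTHS_PX,
) -> List[Tuple[WireSpec, Tuple[int, int]]]:
    """The default validation grid: one straight horizontal wire per canvas
    for every (width, length) combination."""
    out: List[Tuple[WireSpec, Tuple[int, int]]] = []
    for w in widths_px:
        for L in lengths_px:
            margin = max(30, w * 3)
            canvas = (2 * margin, L + 2 * margin)
            y = float(margin)
            wire = WireSpec(path=((float(margin), y), (float(margin + L), y)), width_px=w)
            out.append((wire, canvas))
    return out
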