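"""Grayscale preprocessing and binary segmentation of root scans.

The pipeline expects dark roots on a light background.  Preprocessing is
grayscale conversion, median smoothing, and intensity inversion, after
which the root is the *bright* phase and every thresholding routine here
uniformly treats "foreground" as the pixels above the (global or local)
threshold.  Four automatic threshold methods are provided — Otsu,
triangle, adaptive mean, and adaptive Gaussian — followed by
connected-component particle clearance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.measure import label

from .errors import DegenerateHistogramError, FormatError, InvalidArgumentError

logger = logging.getLogger(__name__)

# ITU-R BT.601 luma weights, the convention used by PIL's "L" conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

Method = Literal["otsu", "triangle", "adaptive_mean", "adaptive_gaussian", "manual"]

__all__ = [
    "GrayImage",
    "BinaryMask",
    "SegmentationConfig",
    "to_grayscale",
    "median_smooth",
    "invert",
    "threshold_otsu",
    "threshold_triangle",
    "threshold_adaptive",
    "remove_small_components",
    "segment",
]


@dataclass(frozen=True)
class GrayImage:
    """A single-channel 8-bit intensity raster with optional DPI metadata."""

    pixels: np.ndarray
    dpi: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise FormatError(f"GrayImage must be 2-D and at least 2x2, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FormatError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.dpi is not None and self.dpi <= 0:
            raise InvalidArgumentError(f"dpi must be positive, got {self.dpi}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """Boolean raster; True marks root foreground."""

    pixels: np.ndarray
    provenance: Method = "manual"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"BinaryMask must be 2-D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class SegmentationConfig:
    """Knobs for the segmentation stage.

    ``method`` selects the thresholding routine; ``None`` requests the
    default per-trait pairing (triangle for length, Otsu for the
    distance-transform traits).  ``block_size``/``offset_c`` apply to the
    adaptive methods only.
    """

    method: Optional[Method] = None
    median_kernel: int = 3
    invert: bool = True
    block_size: int = 11
    offset_c: float = 2.0
    min_particle_area: int = 50
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise InvalidArgumentError(f"median_kernel must be odd >= 1, got {self.median_kernel}")
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise InvalidArgumentError(f"block_size must be odd >= 3, got {self.block_size}")
        if self.min_particle_area < 0:
            raise InvalidArgumentError("min_particle_area must be >= 0")
        if self.connectivity not in (4, 8):
            raise InvalidArgumentError(f"connectivity must be 4 or 8, got {self.connectivity}")


def to_grayscale(image: np.ndarray, dpi: Optional[float] = None) -> GrayImage:
    """Convert a 1- or 3-channel raster to a luminance :class:`GrayImage`.

    RGB input is collapsed with the BT.601 weights (0.299, 0.587, 0.114);
    single-channel input passes through unchanged.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return GrayImage(arr, dpi=dpi)
    if arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr.astype(np.float64) @ np.array(LUMA_WEIGHTS)
        return GrayImage(np.clip(np.rint(gray), 0, 255).astype(np.uint8), dpi=dpi)
    if arr.ndim == 3 and arr.shape[2] == 4:
        # alpha ignored; scanners never emit meaningful alpha
        return to_grayscale(arr[:, :, :3], dpi=dpi)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return GrayImage(arr[:, :, 0], dpi=dpi)
    raise FormatError(f"unsupported image layout with shape {arr.shape}")


def median_smooth(g: GrayImage, kernel: int = 3) -> GrayImage:
    """Median-filter with a ``kernel x kernel`` window (edge-replicated).

    ``kernel=1`` is the identity.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise InvalidArgumentError(f"median kernel must be odd >= 1, got {kernel}")
    if kernel == 1:
        return g
    out = ndimage.median_filter(g.pixels, size=kernel, mode="nearest")
    return GrayImage(out, dpi=g.dpi)


def invert(g: GrayImage) -> GrayImage:
    """Map every intensity v to 255 - v."""
    return GrayImage(255 - g.pixels, dpi=g.dpi)


def _histogram256(pixels: np.ndarray) -> np.ndarray:
    return np.bincount(pixels.ravel(), minlength=256).astype(np.float64)


def threshold_otsu(g: GrayImage) -> Tuple[BinaryMask, int]:
    """Global Otsu threshold on the 256-bin histogram.

    Returns the mask of pixels *above* the threshold (the root phase of an
    inverted scan) and the threshold itself.  The threshold maximizes the
    between-class variance ``w0*w1*(mu0-mu1)^2`` over classes
    ``{<= t}`` / ``{> t}``; ties resolve to the smallest t.
    """
    hist = _histogram256(g.pixels)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("Otsu thresholding needs >= 2 distinct intensities")
    t = _otsu_from_histogram(hist)
    return BinaryMask(g.pixels > t, provenance="otsu"), t


def _otsu_from_histogram(hist: np.ndarray) -> int:
    p = hist / hist.sum()
    omega0 = np.cumsum(p)                      # weight of class {<= t}
    mu_t = np.cumsum(p * np.arange(256))       # first moment up to t
    mu_total = mu_t[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu_t) ** 2 / (omega0 * omega1)
    sigma_b[~np.isfinite(sigma_b)] = -1.0      # classes must both be nonempty
    return int(np.argmax(sigma_b))             # argmax takes the smallest tie


def threshold_triangle(g: GrayImage) -> Tuple[BinaryMask, int]:
    """Global triangle threshold on the 256-bin histogram.

    A straight line is drawn from the histogram peak to the far end of the
    longer tail; the threshold is the bin whose histogram point lies
    farthest (perpendicularly) below that line.  Returns the above-threshold
    mask and the threshold.
    """
    hist = _histogram256(g.pixels)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("triangle thresholding needs >= 2 distinct intensities")
    t = _triangle_from_histogram(hist)
    return BinaryMask(g.pixels > t, provenance="triangle"), t


def _triangle_from_histogram(hist: np.ndarray) -> int:
    nonzero = np.nonzero(hist)[0]
    first, last = nonzero[0], nonzero[-1]
    peak = int(np.argmax(hist))  # smallest peak bin on ties
    # Work on the side with the longer baseline from the peak to the
    # farthest nonzero bin; mirror so the tail is always to the right.
    if peak - first >= last - peak:
        h = hist[::-1]
        peak_m = 255 - peak
        tail_m = 255 - first
        mirrored = True
    else:
        h = hist
        peak_m = peak
        tail_m = last
        mirrored = False
    if tail_m == peak_m:
        return int(peak)
    xs = np.arange(peak_m, tail_m + 1, dtype=np.float64)
    ys = h[peak_m : tail_m + 1]
    # Perpendicular distance from (x, h[x]) to the peak->tail chord, up to a
    # positive factor: |cross((tail-peak), (point-peak))|.
    dx = float(tail_m - peak_m)
    dy = float(h[tail_m] - h[peak_m])
    dist = dx * (h[peak_m] - ys) - (-dy) * (xs - peak_m)
    t_m = peak_m + int(np.argmax(dist))
    return int(255 - t_m) if mirrored else int(t_m)


def threshold_adaptive(
    g: GrayImage,
    mode: Literal["mean", "gaussian"],
    block_size: int = 11,
    offset_c: float = 2.0,
    sigma: Optional[float] = None,
) -> BinaryMask:
    """Local adaptive threshold: foreground iff intensity > local statistic + offset_c.

    The local statistic is the plain mean (``mode="mean"``) or
    Gaussian-weighted mean (``mode="gaussian"``) over a
    ``block_size x block_size`` neighborhood.  A positive ``offset_c``
    demands the pixel exceed its neighborhood by that margin, so constant
    regions produce no foreground.  ``sigma`` tunes the Gaussian weighting
    (default: block_size/6 as is conventional); in the large-sigma limit
    the Gaussian statistic converges to the plain block mean.
    """
    if block_size < 3 or block_size % 2 == 0:
        raise InvalidArgumentError(f"block_size must be odd >= 3, got {block_size}")
    if mode not in ("mean", "gaussian"):
        raise InvalidArgumentError(f"adaptive mode must be 'mean' or 'gaussian', got {mode!r}")
    local = threshold_local(
        g.pixels.astype(np.float64), block_size=block_size, method=mode,
        offset=-offset_c, param=sigma if mode == "gaussian" else None,
    )
    provenance = "adaptive_mean" if mode == "mean" else "adaptive_gaussian"
    return BinaryMask(g.pixels > local, provenance=provenance)


def manual_threshold(g: GrayImage, t: int) -> BinaryMask:
    """Fixed global threshold (pixels above t are foreground)."""
    return BinaryMask(g.pixels > t, provenance="manual")


def remove_small_components(m: BinaryMask, min_area: int, connectivity: int = 8) -> BinaryMask:
    """Drop every foreground component with fewer than ``min_area`` pixels.

    ``min_area=0`` is the identity.  The operation is idempotent and never
    grows the foreground.
    """
    if min_area < 0:
        raise InvalidArgumentError(f"min_area must be >= 0, got {min_area}")
    if connectivity not in (4, 8):
        raise InvalidArgumentError(f"connectivity must be 4 or 8, got {connectivity}")
    if min_area <= 1 or not m.pixels.any():
        return BinaryMask(m.pixels.copy(), provenance=m.provenance)
    conn = 1 if connectivity == 4 else 2
    labels, n = label(m.pixels, connectivity=conn, return_num=True)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = counts >= min_area
    keep[0] = False
    return BinaryMask(keep[labels], provenance=m.provenance)


def preprocess(
    image: np.ndarray, config: SegmentationConfig, dpi: Optional[float] = None
) -> GrayImage:
    """Grayscale conversion, median smoothing, and (by default) inversion."""
    g = to_grayscale(image, dpi=dpi)
    g = median_smooth(g, config.median_kernel)
    if config.invert:
        g = invert(g)
    return g


def segment(
    g: GrayImage, config: SegmentationConfig, method: Optional[Method] = None
) -> Tuple[BinaryMask, Optional[int]]:
    """Threshold a preprocessed (root-bright) image and clear small particles.

    Returns the cleaned mask and the global threshold used (None for the
    adaptive methods).
    """
    method = method or config.method or "otsu"
    threshold: Optional[int] = None
    if method == "otsu":
        mask, threshold = threshold_otsu(g)
    elif method == "triangle":
        mask, threshold = threshold_triangle(g)
    elif method == "adaptive_mean":
        mask = threshold_adaptive(g, "mean", config.block_size, config.offset_c)
    elif method == "adaptive_gaussian":
        mask = threshold_adaptive(g, "gaussian", config.block_size, config.offset_c)
    else:
        raise InvalidArgumentError(f"unknown segmentation method {method!r}")
    cleaned = remove_small_components(mask, config.min_particle_area, config.connectivity)
    logger.debug(
        "segment: method=%s threshold=%s foreground %d -> %d px after particle clearance",
        method, threshold, mask.count(), cleaned.count(),
    )
    return cleaned, threshold
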