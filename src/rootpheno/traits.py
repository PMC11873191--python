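"""Calibrated root-trait estimation from masks, skeletons, and distance maps.

Measured traits
---------------
* TRL — total root length: the skeleton is treated as a chain of pixel
  centers; each unique 8-adjacent pixel pair contributes one pixel size for
  an orthogonal step and sqrt(2) (~1.4142) pixel sizes for a diagonal step.
  A diagonal pair is skipped when its two pixels share an orthogonal
  skeleton neighbor completing a triangle, which would otherwise double
  count the path.
* AD — average diameter: the Euclidean distance transform sampled at each
  skeleton pixel gives a local radius r = DT * ps; AD is the mean of 2r.
* SA — surface area: per-pixel circumference 2*pi*r summed and multiplied
  by the pixel size.
* RV — root volume: per-pixel cross-section pi*r^2 summed and multiplied
  by the pixel size.
* PA — projected area: foreground pixel count times ps^2.

Estimated traits (cylinder approximations from PA and TRL)
----------------------------------------------------------
SA_est = PA * pi;  AD_est = PA / TRL;  RV_est = pi * (AD_est / 2)^2 * TRL.

By default :func:`analyze_root` runs two segmentation branches — triangle
threshold for the skeleton feeding TRL, Otsu threshold for the distance
transform feeding AD/SA/RV and PA — which is the pairing that performed
best in validation.  Forcing ``config.method`` runs both branches from a
single method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .calibration import Scale
from .errors import InternalConsistencyError, UndefinedTraitError
from .segmentation import (
    BinaryMask,
    GrayImage,
    SegmentationConfig,
    preprocess,
    segment,
)
from .skeletonization import Skeleton, thin

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)

__all__ = [
    "RootTraits",
    "distance_transform",
    "total_root_length",
    "radii_along_skeleton",
    "average_diameter",
    "surface_area",
    "root_volume",
    "projected_area",
    "estimated_traits",
    "analyze_root",
]


@dataclass(frozen=True)
class RootTraits:
    """Calibrated trait record for one image."""

    trl: float
    ad: float
    sa: float
    rv: float
    projected_area: float
    n_skeleton_pixels: int
    sa_estimated: float
    ad_estimated: float
    rv_estimated: float
    scale: Scale
    thresholds: Dict[str, Optional[int]] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        d = {
            "TRL_cm": self.trl,
            "AD_cm": self.ad,
            "SA_cm2": self.sa,
            "RV_cm3": self.rv,
            "PA_cm2": self.projected_area,
            "SA_est_cm2": self.sa_estimated,
            "AD_est_cm": self.ad_estimated,
            "RV_est_cm3": self.rv_estimated,
            "n_skeleton_pixels": self.n_skeleton_pixels,
            "pixel_size_cm": self.scale.pixel_size,
        }
        for k, v in self.thresholds.items():
            d[f"threshold_{k}"] = v
        return d


def distance_transform(m: BinaryMask) -> np.ndarray:
    """Exact Euclidean distance (pixels) from each foreground pixel to the
    nearest background pixel; zero on the background.

    An all-foreground mask is handled by treating the image border as
    background (one padded ring), so distances stay finite.
    """
    mask = m.pixels
    if mask.all():
        logger.warning("distance_transform: all-foreground mask; border treated as background")
        padded = np.pad(mask, 1)
        return ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return ndimage.distance_transform_edt(mask)


def total_root_length(
    s: Skeleton, scale: Scale, rule: Literal["edges", "pixels"] = "edges"
) -> float:
    """Total root length in cm from a skeleton.

    ``rule="edges"`` (default) sums unique 8-adjacent pixel-pair steps:
    weight 1 per orthogonal pair, sqrt(2) per diagonal pair, with diagonal
    pairs suppressed when an orthogonal skeleton neighbor completes a
    triangle.  A pure diagonal chain therefore measures exactly its
    Euclidean endpoint distance.

    ``rule="pixels"`` is the literal per-pixel variant kept for
    comparability: each skeleton pixel contributes 1, or sqrt(2) when it
    has any diagonal-only link to its neighbors.
    """
    sk = s.pixels
    if not sk.any():
        return 0.0
    p = np.pad(sk, 1).astype(np.uint8)
    c = p[1:-1, 1:-1].astype(bool)
    e = p[1:-1, 2:].astype(bool)    # east neighbor
    so = p[2:, 1:-1].astype(bool)   # south
    se = p[2:, 2:].astype(bool)     # south-east
    sw = p[2:, :-2].astype(bool)    # south-west
    w = p[1:-1, :-2].astype(bool)   # west

    if rule == "edges":
        n_orth = np.count_nonzero(c & e) + np.count_nonzero(c & so)
        # diagonal SE pair (r,c)-(r+1,c+1): triangle via (r,c+1) or (r+1,c)
        diag_se = c & se & ~e & ~so
        # diagonal SW pair (r,c)-(r+1,c-1): triangle via (r,c-1) or (r+1,c)
        diag_sw = c & sw & ~w & ~so
        n_diag = np.count_nonzero(diag_se) + np.count_nonzero(diag_sw)
        n_pixel_units = n_orth + SQRT2 * n_diag
    elif rule == "pixels":
        ne = p[:-2, 2:].astype(bool)
        nw = p[:-2, :-2].astype(bool)
        no = p[:-2, 1:-1].astype(bool)
        has_diag = c & (se | sw | ne | nw) & ~(e | w | so | no)
        n_pixel_units = np.count_nonzero(c & ~has_diag) + SQRT2 * np.count_nonzero(has_diag)
    else:
        raise ValueError(f"unknown length rule {rule!r}")
    return float(n_pixel_units) * scale.pixel_size


def radii_along_skeleton(s: Skeleton, dmap: np.ndarray, scale: Scale) -> np.ndarray:
    """Local radius r = DT * ps at every skeleton pixel, row-major order."""
    sk = s.pixels
    if sk.shape != dmap.shape:
        raise InternalConsistencyError(
            f"skeleton shape {sk.shape} does not match distance map shape {dmap.shape}"
        )
    dt = np.asarray(dmap)[sk]
    if dt.size and dt.min() <= 0:
        raise InternalConsistencyError(
            "skeleton pixel with zero distance-transform value: skeleton lies outside the mask"
        )
    return dt * scale.pixel_size


def average_diameter(radii: Sequence[float]) -> float:
    """AD = sum(2 * r_i) / N over the skeleton pixels."""
    radii = np.asarray(radii, dtype=np.float64)
    if radii.size == 0:
        raise UndefinedTraitError("average diameter is undefined for an empty skeleton")
    return float(2.0 * radii.mean())


def surface_area(radii: Sequence[float], scale: Scale) -> float:
    """SA = ps * sum(2 * pi * r_i)."""
    radii = np.asarray(radii, dtype=np.float64)
    if radii.size == 0:
        logger.warning("surface_area: empty radius list, returning 0")
        return 0.0
    return float(scale.pixel_size * 2.0 * math.pi * radii.sum())


def root_volume(radii: Sequence[float], scale: Scale) -> float:
    """RV = ps * sum(pi * r_i^2)."""
    radii = np.asarray(radii, dtype=np.float64)
    if radii.size == 0:
        logger.warning("root_volume: empty radius list, returning 0")
        return 0.0
    return float(scale.pixel_size * math.pi * np.square(radii).sum())


def projected_area(m: BinaryMask, scale: Scale) -> float:
    """PA = foreground pixel count * ps^2."""
    return float(m.count()) * scale.pixel_size**2


def estimated_traits(pa: float, trl: float) -> Tuple[float, float, float]:
    """Cylinder-model estimates (SA_est, AD_est, RV_est) from PA and TRL."""
    if trl <= 0:
        raise UndefinedTraitError("estimated traits are undefined for zero total root length")
    sa_est = pa * math.pi
    ad_est = pa / trl
    rv_est = math.pi * (ad_est / 2.0) ** 2 * trl
    return sa_est, ad_est, rv_est


def _zero_traits(scale: Scale, thresholds: Dict[str, Optional[int]]) -> RootTraits:
    return RootTraits(
        trl=0.0, ad=0.0, sa=0.0, rv=0.0, projected_area=0.0, n_skeleton_pixels=0,
        sa_estimated=0.0, ad_estimated=0.0, rv_estimated=0.0,
        scale=scale, thresholds=thresholds,
    )


def analyze_root(
    image: np.ndarray,
    config: SegmentationConfig,
    scale: Scale,
    length_rule: Literal["edges", "pixels"] = "edges",
) -> RootTraits:
    """Run the full trait pipeline on a raw image.

    Preprocessing (grayscale, median smooth, invert) is shared; by default
    the triangle threshold drives skeletonization/TRL and the Otsu
    threshold drives the distance-transform traits and PA.  A forced
    ``config.method`` runs both branches from that single method.
    """
    g = preprocess(image, config)
    if np.ptp(g.pixels) == 0:
        logger.warning("analyze_root: constant (blank) image, all traits zero")
        return _zero_traits(scale, {})

    trl_method = config.method or "triangle"
    dt_method = config.method or "otsu"

    trl_mask, trl_threshold = segment(g, config, method=trl_method)
    if trl_method == dt_method:
        dt_mask, dt_threshold = trl_mask, trl_threshold
    else:
        dt_mask, dt_threshold = segment(g, config, method=dt_method)
    thresholds = {trl_method: trl_threshold, dt_method: dt_threshold}

    if not dt_mask.pixels.any() and not trl_mask.pixels.any():
        logger.warning("analyze_root: empty mask after segmentation, all traits zero")
        return _zero_traits(scale, thresholds)

    trl_skeleton = thin(trl_mask)
    trl = total_root_length(trl_skeleton, scale, rule=length_rule)

    dt_skeleton = thin(dt_mask) if dt_mask is not trl_mask else trl_skeleton
    dmap = distance_transform(dt_mask)
    radii = radii_along_skeleton(dt_skeleton, dmap, scale)
    if radii.size:
        ad = average_diameter(radii)
        sa = surface_area(radii, scale)
        rv = root_volume(radii, scale)
    else:
        ad = sa = rv = 0.0
    pa = projected_area(dt_mask, scale)

    if trl > 0:
        sa_est, ad_est, rv_est = estimated_traits(pa, trl)
    else:
        sa_est = ad_est = rv_est = 0.0

    return RootTraits(
        trl=trl, ad=ad, sa=sa, rv=rv, projected_area=pa,
        n_skeleton_pixels=trl_skeleton.count(),
        sa_estimated=sa_est, ad_estimated=ad_est, rv_estimated=rv_est,
        scale=scale, thresholds=thresholds,
    )
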