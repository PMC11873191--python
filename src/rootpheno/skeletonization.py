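"""Morphological thinning of binary root masks to one-pixel skeletons.

Implements the Zhang-Suen two-subiteration parallel thinning rules: the
mask boundary is peeled iteratively until no pixel is deletable, leaving a
connectivity-preserving medial curve.  A sequential simple-point cleanup
pass then removes any residual pixel participating in a 2x2 foreground
block, so the output is strictly one pixel wide.  No spur pruning is
performed, so short laterals survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .segmentation import BinaryMask

logger = logging.getLogger(__name__)

__all__ = ["Skeleton", "thin"]


@dataclass(frozen=True)
class Skeleton:
    """One-pixel-wide boolean medial curve raster."""

    pixels: np.ndarray
    source_mask_shape: Tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels).astype(bool))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())

    def coordinates(self) -> np.ndarray:
        """Row-major (row, col) coordinates of skeleton pixels."""
        return np.argwhere(self.pixels)


def _neighborhoods(img: np.ndarray):
    """The eight neighbor rasters P2..P9 (N, NE, E, SE, S, SW, W, NW) of a
    zero-padded image's interior."""
    c = img[1:-1, 1:-1]
    p2 = img[:-2, 1:-1]
    p3 = img[:-2, 2:]
    p4 = img[1:-1, 2:]
    p5 = img[2:, 2:]
    p6 = img[2:, 1:-1]
    p7 = img[2:, :-2]
    p8 = img[1:-1, :-2]
    p9 = img[:-2, :-2]
    return c, (p2, p3, p4, p5, p6, p7, p8, p9)


def _zhang_suen_pass(padded: np.ndarray, step: int) -> bool:
    """One parallel subiteration; returns True if any pixel was deleted."""
    c, (p2, p3, p4, p5, p6, p7, p8, p9) = _neighborhoods(padded)
    ring = np.stack([p2, p3, p4, p5, p6, p7, p8, p9, p2]).astype(np.int8)
    b = ring[:-1].sum(axis=0)
    a = ((ring[:-1] == 0) & (ring[1:] == 1)).sum(axis=0)
    if step == 0:
        cond = (p2 * p4 * p6 == 0) & (p4 * p6 * p8 == 0)
    else:
        cond = (p2 * p4 * p8 == 0) & (p2 * p6 * p8 == 0)
    delete = (c == 1) & (b >= 2) & (b <= 6) & (a == 1) & cond
    if not delete.any():
        return False
    c[delete] = 0
    return True


# 8-neighborhood offsets in Zhang-Suen ring order (P2..P9).
_RING = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _is_simple(padded: np.ndarray, r: int, c: int) -> bool:
    """True if deleting (r, c) keeps local 8-connectivity (crossing number 1)
    and the pixel is not an endpoint."""
    ring = [int(padded[r + dr, c + dc]) for dr, dc in _RING]
    b = sum(ring)
    if b < 2:
        return False
    ring.append(ring[0])
    a = sum(1 for i in range(8) if ring[i] == 0 and ring[i + 1] == 1)
    return a == 1


def _collapse_squares(padded: np.ndarray) -> None:
    """Sequentially delete simple points that sit in 2x2 foreground blocks.

    Zhang-Suen occasionally leaves 2x2 blocks at staircase junctions; each
    deletion here is a simple-point removal, so topology is untouched.
    """
    changed = True
    while changed:
        changed = False
        blocks = (
            padded[:-1, :-1] & padded[:-1, 1:] & padded[1:, :-1] & padded[1:, 1:]
        )
        for r, c in np.argwhere(blocks):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if padded[rr, cc] and _is_simple(padded, rr, cc):
                    padded[rr, cc] = 0
                    changed = True
                    break


def thin(m: BinaryMask) -> Skeleton:
    """Thin a binary mask to a one-pixel-wide skeleton.

    The mask is padded with one background ring during iteration (so
    edge-touching roots thin cleanly) and cropped afterwards.  An empty
    mask yields an empty skeleton.
    """
    mask = m.pixels
    if not mask.any():
        logger.info("thin: empty mask, returning empty skeleton")
        return Skeleton(np.zeros_like(mask, dtype=bool), source_mask_shape=mask.shape)
    padded = np.pad(mask, 1).astype(np.uint8)
    while True:
        changed = _zhang_suen_pass(padded, 0)
        changed |= _zhang_suen_pass(padded, 1)
        if not changed:
            break
    _collapse_squares(padded)
    skeleton = padded[1:-1, 1:-1].astype(bool)
    skeleton = _restore_vanished_components(mask, skeleton)
    return Skeleton(skeleton, source_mask_shape=mask.shape)


def _restore_vanished_components(mask: np.ndarray, skeleton: np.ndarray) -> np.ndarray:
    """Re-seed one medial pixel for any mask component the parallel thinning
    deleted outright (it can erase e.g. isolated 2x2 squares), keeping the
    foreground component count exactly preserved."""
    from scipy import ndimage

    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return skeleton
    surviving = np.unique(labels[skeleton])
    missing = np.setdiff1d(np.arange(1, n + 1), surviving)
    if missing.size:
        logger.debug("thin: restoring %d vanished component(s)", missing.size)
        dist = ndimage.distance_transform_edt(mask)
        for lab in missing:
            component = labels == lab
            flat = np.where(component.ravel(), dist.ravel(), -1.0)
            skeleton.ravel()[int(flat.argmax())] = True
    return skeleton
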