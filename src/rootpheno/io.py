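"""Image reading/writing with DPI metadata handling (PNG/TIFF/JPEG)."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from PIL import Image

from .errors import FormatError

logger = logging.getLogger(__name__)

SUPPORTED_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}

__all__ = ["read_image", "write_binary_png", "SUPPORTED_SUFFIXES"]


def read_image(path: Union[str, Path]) -> Tuple[np.ndarray, Optional[float]]:
    """Load an image as a uint8 array (2-D gray or HxWx3 RGB) plus its DPI.

    DPI is taken from the file's resolution metadata when present (the
    horizontal value; scanners write isotropic resolutions) and is None
    otherwise.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            dpi = None
            info_dpi = im.info.get("dpi")
            if info_dpi:
                dpi = float(info_dpi[0]) if isinstance(info_dpi, (tuple, list)) else float(info_dpi)
                if dpi <= 1:  # PIL reports 1 or 0 for "unset"
                    dpi = None
            if im.mode in ("L", "RGB"):
                arr = np.asarray(im)
            elif im.mode in ("I;16", "I;16B", "I"):
                arr16 = np.asarray(im).astype(np.float64)
                arr = np.clip(np.rint(arr16 / 257.0), 0, 255).astype(np.uint8)
            else:
                arr = np.asarray(im.convert("RGB"))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    return arr, dpi


def write_binary_png(
    pixels: np.ndarray, path: Union[str, Path], dpi: Optional[float] = None
) -> None:
    """Write a boolean raster as an 8-bit PNG with foreground = 255."""
    arr = (np.asarray(pixels).astype(bool) * np.uint8(255))
    im = Image.fromarray(arr, mode="L")
    kwargs = {}
    if dpi is not None:
        kwargs["dpi"] = (dpi, dpi)
    im.save(Path(path), **kwargs)


def write_gray_png(
    pixels: np.ndarray, path: Union[str, Path], dpi: Optional[float] = None
) -> None:
    """Write a uint8 grayscale raster as PNG, carrying DPI metadata."""
    im = Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="L")
    kwargs = {}
    if dpi is not None:
        kwargs["dpi"] = (dpi, dpi)
    im.save(Path(path), **kwargs)
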