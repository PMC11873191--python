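"""Run configuration: scale resolution, key-value config files, precedence.

Precedence is CLI flags > config file > defaults.  Exactly one scale source
(--dpi, --pixel-size, --ruler, or image DPI metadata) must resolve per run;
an explicit flag beats image metadata, with a logged notice when both are
present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

from .calibration import Scale, scale_from_dpi, scale_from_ruler
from .errors import InvalidArgumentError
from .segmentation import SegmentationConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config_file", "resolve_scale"]


@dataclass
class RunConfig:
    """Effective configuration for one batch run."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    dpi: Optional[float] = None
    pixel_size: Optional[float] = None
    ruler: Optional[Tuple[float, float, float, float, float]] = None
    length_rule: str = "edges"
    save_mask: bool = False
    save_skeleton: bool = False
    seed: int = 0

    def as_dict(self) -> Dict[str, object]:
        seg = self.segmentation
        return {
            "method": seg.method or "triangle+otsu",
            "median_kernel": seg.median_kernel,
            "block_size": seg.block_size,
            "offset_c": seg.offset_c,
            "min_particle_area": seg.min_particle_area,
            "connectivity": seg.connectivity,
            "dpi": self.dpi,
            "pixel_size": self.pixel_size,
            "ruler": list(self.ruler) if self.ruler else None,
            "length_rule": self.length_rule,
        }


_CONFIG_KEYS = {
    "method", "median_kernel", "block_size", "offset_c", "min_particle_area",
    "connectivity", "dpi", "pixel_size", "length_rule",
}


def load_config_file(path: Union[str, Path]) -> Dict[str, str]:
    """Parse a plain ``key = value`` config file; '#' starts a comment."""
    values: Dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidArgumentError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise InvalidArgumentError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = value
    return values


def resolve_scale(cfg: RunConfig, image_dpi: Optional[float] = None) -> Scale:
    """Resolve the pixel calibration for a run.

    Explicit sources (pixel-size, ruler, dpi flag) beat image metadata; if
    several explicit sources are given the run is ambiguous and rejected.
    """
    explicit = [s for s in ("dpi", "pixel_size", "ruler") if getattr(cfg, s) is not None]
    if len(explicit) > 1:
        raise InvalidArgumentError(
            f"ambiguous calibration: {' and '.join(explicit)} both given; supply exactly one"
        )
    if cfg.pixel_size is not None:
        scale = Scale.from_pixel_size(cfg.pixel_size)
    elif cfg.ruler is not None:
        x1, y1, x2, y2, cm = cfg.ruler
        scale = scale_from_ruler((x1, y1), (x2, y2), cm)
    elif cfg.dpi is not None:
        scale = scale_from_dpi(cfg.dpi)
    elif image_dpi is not None:
        return scale_from_dpi(image_dpi)
    else:
        raise InvalidArgumentError(
            "no calibration available: pass --dpi, --pixel-size or --ruler, "
            "or use images with DPI metadata"
        )
    if image_dpi is not None:
        logger.info(
            "image carries DPI metadata (%s) but an explicit scale was supplied; using the explicit scale",
            image_dpi,
        )
    return scale
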