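"""Batch driver: analyze a directory of scans into a trait table.

Per-image failures are logged and skipped rather than aborting the run.
The CSV carries run metadata as ``#``-prefixed header comments (values at
6 significant digits); a sidecar JSON holds full-precision values and the
effective configuration.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .config import RunConfig, resolve_scale
from .errors import EmptyInputError, RootPhenoError
from .io import SUPPORTED_SUFFIXES, read_image, write_binary_png
from .segmentation import preprocess, segment
from .skeletonization import thin
from .traits import analyze_root

logger = logging.getLogger(__name__)

__all__ = ["collect_images", "run_batch", "write_trait_table"]


def collect_images(inputs: Sequence[Union[str, Path]]) -> List[Path]:
    """Expand files/directories into a sorted list of readable image paths."""
    paths: List[Path] = []
    for item in inputs:
        p = Path(item)
        if p.is_dir():
            paths.extend(q for q in sorted(p.iterdir()) if q.suffix.lower() in SUPPORTED_SUFFIXES)
        elif p.suffix.lower() in SUPPORTED_SUFFIXES:
            paths.append(p)
    if not paths:
        raise EmptyInputError(f"no readable images found under {list(map(str, inputs))}")
    return paths


def run_batch(
    cfg: RunConfig,
    inputs: Sequence[Union[str, Path]],
    out_csv: Union[str, Path],
    intermediates_dir: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Analyze every image and write the trait table plus a sidecar JSON."""
    paths = collect_images(inputs)
    rows: List[Dict[str, object]] = []
    skipped: List[str] = []
    for path in paths:
        try:
            arr, image_dpi = read_image(path)
            scale = resolve_scale(cfg, image_dpi=image_dpi)
            traits = analyze_root(arr, cfg.segmentation, scale, length_rule=cfg.length_rule)
            row: Dict[str, object] = {"filename": path.name}
            row.update(traits.as_dict())
            rows.append(row)
            if intermediates_dir and (cfg.save_mask or cfg.save_skeleton):
                _save_intermediates(arr, cfg, path, Path(intermediates_dir))
        except RootPhenoError as exc:
            logger.error("skipping %s: %s", path, exc)
            skipped.append(path.name)
    if not rows:
        raise EmptyInputError("every input image failed to analyze")
    table = pd.DataFrame(rows)
    write_trait_table(table, out_csv, cfg, skipped=skipped)
    return table


def _save_intermediates(arr, cfg: RunConfig, src: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    g = preprocess(arr, cfg.segmentation)
    for method in ({cfg.segmentation.method} if cfg.segmentation.method else {"triangle", "otsu"}):
        mask, _ = segment(g, cfg.segmentation, method=method)
        if cfg.save_mask:
            write_binary_png(mask.pixels, outdir / f"{src.stem}_{method}_mask.png")
        if cfg.save_skeleton:
            write_binary_png(thin(mask).pixels, outdir / f"{src.stem}_{method}_skeleton.png")


def write_trait_table(
    table: pd.DataFrame,
    out_csv: Union[str, Path],
    cfg: RunConfig,
    skipped: Sequence[str] = (),
) -> None:
    """CSV with '#' metadata header (6 s.f.) + full-precision sidecar JSON."""
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__, "config": cfg.as_dict(), "skipped": list(skipped)}
    header = "".join(f"# {k}: {json.dumps(v)}\n" for k, v in meta.items())
    body = table.to_csv(index=False, float_format="%.6g")
    out_csv.write_text(header + body)
    sidecar = out_csv.with_suffix(".json")
    payload = {"metadata": meta, "rows": table.to_dict(orient="records")}
    sidecar.write_text(json.dumps(payload, indent=2, default=str))


def read_trait_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a trait/reference CSV, tolerating '#' metadata comments."""
    return pd.read_csv(path, comment="#")
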