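# rootpheno

Automated 2-D root-image phenotyping for scanned root systems (dark roots
on a light background). The pipeline segments a grayscale scan with one of
four automatic thresholding methods (Otsu, triangle, adaptive mean,
adaptive Gaussian), clears small noise particles, thins the mask to a
one-pixel skeleton, and computes calibrated root traits:

- **TRL** — total root length, from 8-connected skeleton steps (orthogonal
  steps weigh 1 pixel, diagonal steps weigh √2 ≈ 1.4142);
- **AD** — average diameter, from the Euclidean distance transform sampled
  at skeleton pixels (`r = DT × pixel_size`, `AD = mean(2r)`);
- **SA** — surface area, `pixel_size × Σ 2πrᵢ`;
- **RV** — root volume, `pixel_size × Σ πrᵢ²`;
- **PA** — projected area, plus cylinder-model *estimated* variants
  (`SA_est = PA·π`, `AD_est = PA/TRL`, `RV_est = π(AD_est/2)²·TRL`).

By default the triangle threshold drives skeletonization/TRL and the Otsu
threshold drives the distance-transform traits — the pairing that
performed best in validation — and both branches share the preprocessing
(grayscale → median blur → inversion). Calibration comes from scanner DPI
(`pixels/cm = dpi / 2.54`) or a two-point ruler measurement. Built-in
agreement statistics (RMSE, MBE, R²) and a synthetic wire-phantom
generator with closed-form ground truth support validation end to end.

## CLI

```bash
# calibration helpers
rootpheno calibrate --dpi 400
rootpheno calibrate --ruler 0,0,158,0,1        # p1x,p1y,p2x,p2y,cm

# generate ground-truth wire phantoms + truth.csv
rootpheno make-fixtures --out fixtures/ --dpi 400 --seed 42

# batch trait analysis (PNG/TIFF/JPEG)
rootpheno analyze fixtures/ --out traits.csv --dpi 400
rootpheno analyze scans/ --out traits.csv --pixel-size 0.0063 \
    --method otsu --median-kernel 3 --min-particle-area 50 \
    --save-mask --save-skeleton

# RMSE / MBE / R² against a reference table keyed on filename
rootpheno compare traits.csv fixtures/truth.csv --traits TRL_cm,AD_cm --out report.csv
```

`analyze` writes one CSV row per image (6 significant digits, run
metadata as `#` comments) plus a full-precision sidecar JSON. Per-image
failures are logged and skipped. Exit codes: 0 success, 1 usage error,
2 data error. A plain `key = value` config file can be passed with
`--config`; explicit CLI flags win.

## Layout

- `src/rootpheno/calibration.py` — DPI / two-point ruler pixel calibration
- `src/rootpheno/segmentation.py` — preprocessing, four auto-thresholds, particle clearance
- `src/rootpheno/skeletonization.py` — Zhang–Suen thinning to 1-px skeletons
- `src/rootpheno/traits.py` — TRL/AD/SA/RV/PA and estimated traits
- `src/rootpheno/validation_metrics.py` — RMSE, MBE, R² and table comparison
- `src/rootpheno/synthetic_fixtures.py` — wire phantoms and synthetic rulers
- `src/rootpheno/cli.py`, `batch.py`, `config.py`, `io.py` — batch driver and CLI
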