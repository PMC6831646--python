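# hypertrait

Hyperspectral prediction and pixel-level mapping of water and nitrogen
content in wheat.

High-throughput phenotyping platforms image potted plants with dual
line-scanning hyperspectral cameras — VNIR (400–1000 nm) and SWIR
(1000–2500 nm) — producing, per plant, a raw datacube plus dark and white
reference frames.  `hypertrait` turns those products into trait predictions
and per-pixel trait maps for plant scientists and breeders who need
non-destructive estimates of plant water status and nitrogen nutrition:

1. **Calibration** — `R = (I_raw − I_dark)/(I_white − I_dark)` per element.
2. **Segmentation** — vegetation pixels via an enhanced vegetation index
   threshold (EVI = 2.5(R_NIR − R_R)/(R_NIR + 6R_R − 7.5R_B + 1) > 0.25) on
   VNIR cubes, or a hyper-hue + one-class SVM route for SWIR cubes.
3. **Fusion** — per-plant mean spectra from both cameras concatenated with
   the 996–1006 nm overlap removed (optional splice correction).
4. **Chemometrics** — ten preprocessing treatments (raw, Savitzky–Golay
   smoothing and derivatives on reflectance or absorbance, MSC, EMSC, SNV,
   range normalization).
5. **Regression** — PLSR, PCR, ridge MLR, SVR and random forest with
   replicate-based train/validation splits; models graded by R², RMSE and
   RPD = sd(y)/RMSE; wavelength selection by top-30% |β| or by known
   absorption-feature windows.
6. **Mapping** — a linear model's coefficient vector applied to every
   vegetation pixel of a calibrated VNIR cube, rendered as a distribution
   map.

Because raw glasshouse imagery is rarely shippable, the package includes a
first-class **synthetic scene generator** (`hypertrait.scene`) that renders
seeded dual-camera scenes — rosette plants with base-to-tip water gradients
on a soil background, with dark/white frames, sensor noise, per-scene
scatter and ground-truth masks and trait maps — so the whole pipeline is
testable against known truth.  See `docs/methods.md` for the models and
their assumptions.

## Worked example

Simulate a 108-pot trial (2 varieties × 9 soils × 2 watering treatments ×
3 replicates, 48 × 48 px scenes), fit water models on raw and SNV-corrected
spectra, and refit after coefficient-based wavelength selection:

```python
from hypertrait import ExperimentConfig, run_experiment

cfg = ExperimentConfig(
    out_dir="run", seed=1, n_replicates=3,
    varieties=("Gladius", "Kukri"), scene_size=48,
    traits=("water",), methods=("plsr",), treatments=("RAW", "SNV"),
)
res = run_experiment(cfg)
print(res.traits["water"].metrics.to_string(index=False))
mt, mv = res.traits["water"].refit_metrics["coef_fraction"]
print(f"top-30% coefficient selection: validation R2={mv.r2:.3f} "
      f"RMSE={mv.rmse:.3f} RPD={mv.rpd:.2f}")
```

prints

```
trait treatment method  partition       r2     rmse       rpd  n
water       RAW   plsr      train 0.997666 0.300856 20.846350 72
water       RAW   plsr validation 0.996257 0.380663 16.475292 36
water       SNV   plsr      train 0.999757 0.097148 64.558671 72
water       SNV   plsr validation 0.998975 0.207302 30.253203 36
top-30% coefficient selection: validation R2=0.999 RMSE=0.213 RPD=29.48
```

Each row grades one preprocessing × model combination on one partition:
R² is the squared correlation between predicted and reference water content,
RMSE is in water-percent units, and RPD is the ratio of the reference
standard deviation to the RMSE (higher is better; values this high reflect
the synthetic scenes' known truth, not real-glasshouse difficulty).  The
run directory also contains the design and chemistry tables, serialized
models (JSON), selected-wavelength lists, distribution-map PNGs for one
watered and one drought plant, and a run log.

The same pipeline is scriptable from the shell:

```bash
hypertrait simulate -r 1 -s 42 -o scenes --scene-size 64x64 --n-scenes 4
hypertrait segment --raw scenes/pot_0001/vnir_raw.bil \
    --dark scenes/pot_0001/vnir_dark.bil --white scenes/pot_0001/vnir_white.bil \
    --out mask.txt
hypertrait run --config config.yaml --seed 42 --out run/
hypertrait map --model run/model_water_map.json --raw scenes/pot_0001/vnir_raw.bil \
    --dark scenes/pot_0001/vnir_dark.bil --white scenes/pot_0001/vnir_white.bil \
    --out map.png
```

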