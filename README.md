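# pigmorph

Contactless body-weight estimation for pigs from top-view imagery, starting
where segmentation ends: given a **binary dorsal mask** (the animal's back
seen from directly above, white on black), `pigmorph` extracts 17
phenotypic shape features and evaluates how well standard regressors
predict body weight from them under identity-safe data splits.  It is
aimed at agricultural-vision researchers who have a mask-producing
segmentation pipeline and need the downstream morphometry + evaluation
machinery to be correct, deterministic and testable.

## The features

For a mask f(x, y) ∈ {0, 1}:

- size: `mask_area` (Σf), `perimeter`, `longest`/`shortest` (extreme
  contiguous chords through the area centroid — body length and width);
- posture/concavity corrections: `Convex_Hull_Area`, `difference` =
  hull − area, `dif_over_mask`, `body_curve` (interior angle at the
  skeleton's bend vertex between its two endpoints; 180° = straight),
  `outline_curve` (maximum discrete contour curvature);
- the seven Hu moment invariants φ₁…φ₇, built from normalized central
  moments η_pq = μ_pq/μ₀₀^{1+(p+q)/2} (e.g. φ₁ = η₂₀ + η₀₂), invariant to
  translation, scale and rotation;
- `height`: the camera height in metres, carried as a raw calibration
  feature (pixel size scales as 1/height; the regressor learns the
  interaction).

A seeded synthetic herd generator (bent-capsule silhouettes, two camera
heights, an allometric weight law w = α(L·W)^γ·e^ε) provides corpora with
known ground truth; the regression harness implements MAE/MSE/RMSE/R²,
grouped 6:2:2 splitting (no animal in more than one subset), grid-searched
backends (linear, RBF-SVR, linear SVR, random forest, XGBoost, LightGBM),
feature-importance ablations and the Pearson correlation matrix.
See `docs/methods.md` for definitions, algorithms and caveats.

## Worked example

```
pigmorph simulate --n-animals 100 --images-per-animal 10 --seed 42 --out herd/
pigmorph extract  --masks herd/ --meta herd/meta.csv --out features.csv
pigmorph train    --features features.csv --model xgboost --seed 42 --out report.json
pigmorph correlate --features features.csv --out corr.csv
```

On this corpus the grouped split lands exactly on (0.60, 0.20, 0.20) image
fractions, and the validation-selected XGBoost model reports on the test
set (from `report.json`):

```
MAE 5.80 kg   RMSE 7.72 kg   R² 0.961
```

i.e. typical prediction error under 6 kg across a 33–192 kg weight range,
close to the generator's ~4.3 kg noise floor (the weight law carries 5%
multiplicative noise).  The correlation matrix shows `mask_area` ↔ weight
at r = 0.98 — dorsal area is the dominant predictor — and a negative
height ↔ area correlation (r = −0.15), the pinhole-scaling signature that
motivates carrying camera height as a feature.  Single-mask inspection:

```
$ pigmorph inspect herd/pig000_000.png
area: 78095 px²  degenerate: False
touches border: False
hull area: 93938.4  difference: 15843.4  ratio: 0.2029
perimeter: 1288.63 px
kappa_max: 0.03703 1/px
longest: 419.0 px @ 23°  shortest: 164.8 px @ 90°
body_curve: 99.4°
```

(this animal is strongly bent — `body_curve` ≈ 99° — which is why its
`longest` chord is far below its true body length; exactly the posture
effect the correction features quantify).

Real mask corpora are consumed the same way: a directory of PNG masks plus
a `meta.csv` with `image_id, animal_id, camera_height_m, weight_kg`
columns.  Border-touching or degenerate masks are skipped with a log line
(override with `--allow-border`).

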