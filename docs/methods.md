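# Methods

`pigmorph` estimates livestock body weight from top-view binary dorsal
masks.  It has two halves: a deterministic morphometry engine that turns a
silhouette into 17 phenotypic features, and an evaluation harness that
measures how well standard regressors map those features to weight under
identity-safe data splits.  A synthetic herd generator with analytic ground
truth ties the two together for testing.

## The feature set

Every mask is a 2-D grid of {0, 1} (nominally 960 × 540 px), foreground
8-connected, background 4-connected, coordinates x = column / y = row with
origin at the top-left pixel center.  All features are reported in pixel
units; physical calibration enters only through the camera-height feature,
which the regressor is free to interact with.

| feature | definition | units |
|---|---|---|
| `mask_area` | foreground pixel count | px² |
| `Convex_Hull_Area` | corrected hull polygon area (below) | px² |
| `difference` | `Convex_Hull_Area − mask_area` | px² |
| `dif_over_mask` | `difference / mask_area` | — |
| `body_curve` | skeleton bend angle (below), 180° = straight | deg |
| `perimeter` | closed contour length (below) | px |
| `outline_curve` | maximum discrete contour curvature | 1/px |
| `longest`, `shortest` | extreme chords through the area centroid | px |
| `Hu_1` … `Hu_7` | Hu invariants of the binary mask, raw scale | — |
| `height` | camera height | m |

### Contour and perimeter

The outer boundary is traced by Moore-neighbour following (holes ignored;
they still subtract from `mask_area`, a documented reading of "area of the
white region" as foreground pixel count — a mask with interior holes is
anomalous input and logs a warning).  The staircase polygon of pixel
centers overestimates smooth boundary lengths by ≈5% (measured on digitized
discs), so `perimeter` applies one periodic moving average of width 3
before summing segment lengths: discs R = 25–100 then land within 1% of
2πR, an axis-aligned square of side 30 gives 114 (vs 116 for the raw
chain), and contours shorter than twice the window are summed raw so tiny
shapes keep their exact chain length.

### Convex hull

The hull is computed over contour points (Qhull).  Because contour points
are pixel centers, the raw shoelace area of the hull underestimates the
pixel-counted area by about half a one-pixel boundary band; we add
`perimeter/2 + 1` (the lattice-point count of Pick's theorem).  With this
correction a convex blob satisfies `difference ≈ 0` — which the
interpretation "smaller difference means less concavity" presumes — and
`difference ≥ 0` holds for every mask, since the corrected area is at least
the number of lattice points inside the hull.

### Chords through the centroid

"Longest and shortest lines through the geometric center" is implemented
as a discrete angular scan: for each direction θ ∈ [0°, 180°) in 1° steps,
rays march from the area centroid at 0.25-px increments with
nearest-pixel lookup until the first background sample; the chord is the
sum of the two opposite ray lengths, so it is the *contiguous* in-mask
segment ("within the mask" read literally).  Ties resolve toward smaller
θ.  The area centroid (not the bounding-box center) defines the anchor; a
strongly concave blob whose centroid falls on background raises an error
unless the nearest-foreground fallback is enabled (the feature extractor
enables it).

### Skeleton bend angle

The blob is thinned (Zhang–Suen-style, via scikit-image) — chosen over the
exact medial axis, which sprouts dense spur branches on digitized shapes.
Side spurs shorter than 10% of the skeleton are pruned; the two endpoints
are the skeleton pixels at maximal geodesic (along-skeleton) distance,
found by a double Dijkstra sweep with unit/√2 edge weights.
`body_curve` is the interior angle at the skeleton's central bend vertex
between the segments to the two endpoints.

Thinning rounds the skeleton's corner at a bend by roughly half the body
width, so reading the vertex directly off the skeleton (e.g. the pixel
nearest the skeleton's coordinate mean, or the geodesic midpoint)
systematically opens the angle — a constructed 90° bend measures ≈ 104°
and ≈ 101° respectively.  The vertex is therefore estimated as the
intersection of total-least-squares lines fitted to the two halves of the
endpoint-to-endpoint path (the central 30% excluded), with a fallback to
the arc-length midpoint when the halves are nearly collinear.  Constructed
bends of 90–180° are then recovered within ~1.5°.  Blobs with
`longest/shortest < 1.2` have no meaningful bend axis and raise a
degenerate-skeleton error.

### Contour curvature

The contour is resampled to 200 points equally spaced by arc length
(fixed count, so κ is comparable across images at a given resolution),
smoothed, and differentiated by periodic central differences:
κ = |x′y″ − y′x″| / (x′² + y′²)^{3/2}.  A single light smoothing pass
leaves enough staircase noise to swamp gentle curvatures (a R = 50 disc
reads 0.088 instead of 0.020); the default of three passes of a width-7
moving average (≈ Gaussian σ 2.8 samples) brings the disc within ~10% of
1/R while flattening a sharp ellipse tip (a = 60, b = 20, κ = a/b² = 0.15)
by only ~10%.  Both window and pass count are configuration.

### Moments

Raw moments M_pq are exact integer sums over foreground pixel coordinates
(no +0.5 center offset — central and normalized moments are translation-
normalized and unaffected); central moments μ_pq, normalized moments
η_pq = μ_pq/μ₀₀^γ with γ = 1 + (p+q)/2, and the seven Hu polynomial
invariants are evaluated directly from their definitions.  φ values are
emitted raw (a signed-log transform is available for conditioning).  The
implementation is cross-checked in the tests against scikit-image's
independent Hu computation to 10⁻⁹ relative.

## Synthetic herd generator

The generator emulates the statistical structure of a two-camera top-view
weighing study; it is the ground-truth supplier for every end-to-end test.

- **Silhouette**: a bent capsule (medial two-segment polyline dilated to a
  constant width) — elongated, rounded ends, adjustable posture.  Pixel
  centers inside the continuous shape become foreground.
- **Per animal** (intrinsic, fixed across its images): body length
  L ~ U(50, 160) cm; width W = 0.28·L·exp(N(0, 0.08²)) — the width
  fraction and jitter are a realism judgement for finisher pigs, chosen
  once; weight = 0.25·(L·W)^0.75·exp(ε), ε ~ N(0, 0.05²), clipped to
  [33.1, 192] kg.  The exponent 0.75 on the L·W area proxy is a
  conventional allometric scaling; α = 0.25 places the weight range at
  ≈ 34–195 kg over the length range.
- **Per image** (pose): bend ∈ U(90°, 180°), rotation ∈ U(−25°, 25°),
  translation jitter, camera height drawn uniformly from {1.78, 1.88} m.
- **Pinhole scaling**: px_per_cm = K/height with K = 7.5 px·m/cm, so the
  largest animal at 1.78 m spans ≈ 674 px of body length (bounding box
  ≈ 863 px with width) — close to filling the 960-px frame while always
  fitting the 540-px height under rotation and bend jitter.  Draws that
  would clip the frame are re-drawn (same RNG stream, deterministic).

What the generator does *not* emulate: segmentation noise (ragged edges,
holes), head/ear/tail appendages, occlusion, non-capsule body shapes, and
— importantly — any weight signal beyond the single smooth size index
L·W.  Consequences: passing the end-to-end tests shows the pipeline is
wired correctly and recovers a known generative law near its noise floor;
it does **not** show that tree ensembles beat linear regression on real
animals, because on this corpus `mask_area` measures L·W almost perfectly
(bending preserves area) and weight is a smooth monotone function of it,
making linear regression near-optimal by construction.  On the reference
herd the measured ordering between XGBoost and linear in fact varies with
the split seed.

## Evaluation harness

- **Metrics**: MAE, MSE, RMSE, R² by their standard formulas; validation
  errors on length mismatch, empty input, or zero-variance y for R².
- **Split**: whole animals are assigned to train/validation/test targeting
  a 6:2:2 image-count ratio.  Animals are stratified into weight
  quintiles, shuffled within strata (seeded), and greedily assigned to the
  subset with the largest relative image deficit; this balances both the
  ratio and the weight distribution.  Disjointness of animals is
  unconditional; empty subsets are repaired by moving the smallest animal
  from the largest subset (with a warning).
- **Model selection**: each backend grid-searches on the training set and
  is selected by *validation MAE* (the headline unit-interpretable
  metric; the selection metric had to be fixed by us).  Test metrics come
  from the validation-selected model without refitting on train+val.
  Grids are small published-style defaults per backend, documented in
  `pigmorph.regression.DEFAULT_GRIDS`; they include strongly regularized
  shallow-boosting options because the synthetic corpus has only ~60
  training animals' worth of independent weight information.
- **Backends**: `linear` (OLS), `svr_rbf` (RBF-kernel SVR), `svm`
  (linear-kernel SV regression — the roster lists SVR and SVM separately
  without distinguishing them, so we make the second linear), and the tree
  ensembles `random_forest`, `xgboost`, `lightgbm`.  Features are fed raw
  to tree models and standardized for linear/kernel models.  `mlp`
  (scikit-learn) is available but not part of the default roster; a TabNet
  backend is declared optional and reported absent unless its package is
  installed.  All backends run single-threaded with propagated seeds so
  reports are reproducible.
- **Ablation**: reports for named drop-sets next to the full-feature
  baseline, with the importance ranking taken from the baseline tree
  model; the CLI exposes drop-the-k-least-important and keep-the-k-top
  modes.
- **Correlation**: the 18 × 18 Pearson matrix over the 17 features plus
  weight; zero-variance columns become NaN rows rather than errors.

## Numerical and degenerate-input policy

Blobs with fewer than 9 pixels or no interior pixel (thinner than ~2 px
everywhere) are rejected by the feature extractor with the failing feature
named.  A single-pixel blob yields a degenerate one-point contour.
Border-touching masks are rejected by default (a QC idea for catching
partially-framed animals) and skipped-with-a-log-line in the batch CLI,
mirroring a manual exclusion step; `--allow-border` overrides.  Area ties
in blob selection break toward the smallest bounding-box top-left corner;
chord-angle ties toward smaller θ.  Contour orientation is normalized
counter-clockwise in the raster (y-down) frame, i.e. non-negative shoelace
signed area on (x, y).

## Problem sizes used in tests and the acceptance script

The reference herd is 100 animals × 10 images on the full 960 × 540
canvas — large enough that split ratios, correlations, and R² are stable,
and the per-class weight range spans the configured 33–192 kg.  The
acceptance script re-simulates this herd from the given seed, extracts all
1000 feature vectors, and trains the four headline backends; feature
extraction dominates the runtime (a few minutes single-threaded).
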