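# Methods

This note records the models, estimator conventions and design choices
behind `tillercount`, in the order the pipeline runs.

## Scene model and what the generator does (and does not) emulate

The synthetic generator (`tillercount.synthetic`) emulates the acquisition
protocol the pipeline targets: a spaced grass bunch mown at ~5 cm, shoot
tips painted white with a roller, photographed perpendicular to the soil
from ~150 cm with a ~50 × 50 cm field of view. Defaults:

| parameter | default | meaning |
|---|---|---|
| `size` | 1500 × 1500 px | ~50 cm field at `mm_per_px = 0.33` |
| `n_tips` | per study, U[15, 356] | realistic per-bunch tiller range |
| tip diameter | 18–30 px (≈ 6–10 mm) | painted blob, paint spreads beyond the stem section; the lower bound keeps every tip above the 200 px² filter (area ≥ ~254 px²) |
| tip eccentricity | 0–0.55 (round habits), 0.55–0.85 (flattened habit) | species profiles; flattened-stem grasses produce visibly eccentric sections |
| tip intensity | 238–255 | white acrylic paint, bright in all bands |
| soil | mean 90, amplitude ±16, correlation length 6 px | equal R/G/B reflectance (channel means within 2 levels), correlated aggregate texture |
| soil speckles | density 5·10⁻⁴, +25–55 intensity, ~3 px | stones/organic flecks; see "Degenerate inputs" |
| leaf fragments | 25 ribbons, 45–130 × 4–9 px, intensity 205–245 | cut leaves that also catch paint |
| debris | 40 blobs, 6–17 px diameter, intensity 185–235 | mostly below the area filter |
| illumination | linear gradient, ±5 levels | residual uneven lighting |
| `overlap_prob` | 0.02 | probability a proposed tip may touch an existing one, exercising the merge failure mode |

All randomness flows from one `numpy` generator seeded per scene; images
are bit-reproducible. The generator does **not** model photorealistic
paint texture, cast shadows, perspective distortion, wind blur, unpainted
or partially painted tips, or green vegetation between shoots. Passing
tests therefore demonstrate that the algorithmic chain is correct and
well-behaved under controlled contrast and shape statistics — not that the
method is robust to every field condition (the acquisition literature's
advice to shoot on overcast days exists precisely because illumination can
break the contrast assumption).

The labelled training sample drawn by `simulate_study` is 20 % of all
segmented objects, pooled across images, mirroring the scale of a
hand-labelled training set (~1200 objects ≈ 20 % of objects in the
original protocol).

## Automatic thresholding

`max_contrast_threshold` implements the maximum-average-contrast criterion
(Köhler 1981). A threshold *s* separates a 4-adjacent pixel pair (p, q)
when min(I_p, I_q) ≤ s < max(I_p, I_q), and the contrast assigned to the
pair is min(|I_p − s|, |I_q − s|); the selected threshold maximises the
mean contrast over the pairs it separates. Ties break toward the lower
threshold (the test suite checks equivalence with exhaustive search). The
implementation aggregates pairs into a 256 × 256 joint histogram, so the
cost is independent of how many pairs the image has once the histogram is
built. A constant image has no separating threshold and raises an error.
One global threshold is applied per photograph — no tiling.

## Segmentation conventions

Foreground is 8-connected (background 4-connected). The opening uses a
disk structuring element of radius 1 by default (radius 0 disables it);
the small-object filter then removes components under 200 px² — the
opening and the explicit area filter are deliberately separate steps so
the 200 px contract is exact regardless of the structuring element.
Objects touching the image border are kept: the photograph covers the
whole bunch, so border tips are real shoots.

## Morphometric estimator conventions

* **Crofton perimeter** — chord counts in 4 directions:
  P = π(n₀ + n₉₀ + (n₄₅ + n₁₃₅)/√2)/4, where n_θ is the number of
  foreground chords along the unit-spacing line family in direction θ
  (diagonal families are spaced 1/√2, hence the renormalisation). By
  Cauchy–Crofton this estimates π × mean width. A 2-direction variant is
  available. The estimator agrees with scikit-image's
  pixel-configuration implementation to rounding on disks and squares;
  like every finite-direction Crofton estimator it underestimates
  axis-aligned polygons (a square reads ~5 % low) while disks are within
  a fraction of a percent.
* **Equivalent-ellipse axes** — from the second central moments of the
  pixel set with the 1/12 per-pixel variance correction; axis lengths are
  4√λ. A collinear pixel set floors the minor axis at 1 px (logged).
* **Convex hull (A_conv, P_conv)** — hull of the boundary pixels'
  *corner* points (pixel (i,j) spans [i,i+1] × [j,j+1]): the hull then
  contains the whole pixel-square union, which guarantees A_conv ≥ A
  exactly and makes axis-aligned rectangles exact.
* **CMA** — minimum interior angle of the hull of boundary-pixel
  *centres*. The corner polygon is not used here: it wraps every sharp
  corner with a unit pixel square whose spurious right angles would floor
  the statistic at π/2.
* **SMD** — the boundary is resampled at 360 equal polar angles about the
  centroid; the radius along a ray is the furthest point whose bilinearly
  interpolated occupancy is ≥ 0.5, marched at 0.25 px steps, and
  SMD = (1/180) Σ |r(θᵢ) − r(θᵢ + π)|. Bilinear occupancy keeps opposite
  rays exactly symmetric on centrally symmetric rasters, so SMD → 0 for
  disks and centred ellipses. The defining formula is sometimes written
  as a bare sum over the N pairs; the text definition ("mean") is used
  here, so the sum form is simply N·SMD. A centroid outside the object
  (crescents) is computed anyway with a logged warning.
* **Feret diameters** — rotating calipers on the hull of boundary-pixel
  centres plus a 0.5 px boundary correction. The centre hull alone reads
  a 40 px rectangle width as 39 px; the corner hull is exact on polygons
  but biases disks outward ~1.4 px, pushing the sphericity of a r = 50 px
  disk to 0.97. The half-pixel correction keeps both shape families
  within ~1 % (disk SF_sfer 0.989–0.995 over r = 50–100; rectangle
  errors ≤ 1.3 %). A 1° angular-grid variant is provided and agrees with
  the calipers to < 0.5 % on moderate-aspect hulls.
* **Units** — pixels throughout; an optional `mm_per_px` scale converts
  lengths and areas, leaving the dimensionless factors untouched.

Degenerate objects (sub-pixel geometry, collinear boundaries) are dropped
from the feature table with their ids logged.

## Collinearity pruning and the discriminant model

VIF_j = 1/(1 − R²_j) with R²_j from an intercept OLS of descriptor j on
the others, computed by least squares directly so that exact collinearity
is reported as an ∞ sentinel rather than a numerical blow-up. Stepwise
deletion removes the largest-VIF descriptor (ties: the later column,
logged) until all survivors are ≤ 10; fewer than two survivors is an
error. On the synthetic feature tables the perimeter/diameter block
(P_conv, FD_max — VIFs in the hundreds to thousands) falls first, matching
the expected collinearity structure of these descriptors.

The classifier is a two-class Fisher discriminant:
w = W⁻¹(μ_shoot − μ_non-shoot) with W the pooled within-class covariance;
the decision point is the midpoint of the projected class means shifted by
the log prior ratio. Priors are empirical by default (non-shoots are the
minority among segmented objects on clean scenes but can dominate
debris-heavy ones) and configurable to equal. Per-variable diagnostics:

* tolerance T_j = 1 − R²(j | other selected variables);
* Wilks' Λ (two classes) from the Mahalanobis distance,
  Λ = 1/(1 + n₁n₂ D²/((n)(n − 2)));
* F-to-remove F_j = (n − p − 1)(Λ₋ⱼ/Λ − 1), the partial F for dropping
  variable j — for p = 1 this reduces to the two-sample squared-t, which
  pins the convention. (Software packages differ in the exact partial-F
  form; this one is reported explicitly in every model file.)

Backward elimination (on by default) repeatedly drops the variable with
the smallest F-to-remove while that F is below 1.0; the selected set,
coefficients, priors, diagnostics and the VIF trace are serialised to
JSON. Different species habits select different descriptor subsets, which
is why models are stored per species key rather than universally.
Objects exactly on the boundary classify as shoot: under-counting is the
costlier error in breeding use. Diagnostics use a least-squares
(pseudo-inverse) Mahalanobis solve so they stay finite on near-singular
covariances; the model fit itself refuses a singular pooled covariance and
advises stronger pruning.

## Agreement statistics

For paired manual/estimated counts: RMSE = √(Σ(E−O)²/n), MAE = Σ|E−O|/n,
MSE = Σ(E−O)²/n, and the signed mean bias MBE = Σ(E−O)/n. Both MSE and
MBE are reported because the squared form sometimes appears in print
under the "bias" label; keeping both keys removes the ambiguity. The
coefficient of determination is taken against the identity line,
R² = 1 − Σ(O−E)²/Σ(O−Ō)², which penalises miscalibration and is bounded
above by the squared Pearson correlation. The regression of E on O is
OLS; slope = 1 and intercept = 0 are tested with single-constraint F
tests (squared t). A perfect fit has zero residual variance, where the
tests are undefined; both p-values are then reported as 1 (logged).

## Degenerate inputs and numerical edge cases

* Constant grey image → thresholding error (no separating threshold).
* Empty mask → zero objects; empty feature table → count E = 0.
* Featureless soil: on a truly object-free unimodal image the
  maximum-contrast criterion is ill-posed — any threshold is as good as
  another and the mask can flood. The generator's soil therefore carries
  sparse punctate speckles (realistic for soil) that anchor the threshold
  above the soil bulk; every speckle is far below the 200 px filter, so
  empty scenes segment to zero objects, and with tips present the
  threshold still falls in the soil/paint intensity gap.
* Seeds: every stochastic routine takes an explicit seed; the default
  used in examples and tests is 20130913 (arbitrary). Study seeds spawn
  per-scene seeds below 2³¹.

## Problem sizes

The validation study runs 60 scenes at the default 1500 × 1500 px with
true counts uniform in [15, 356] — around 13 000 segmented objects, of
which ~20 % (≈ 2 500) form the training sample. This is large enough for
stable regression statistics while keeping a full run at about a minute
on one CPU.

## Known limitations

* Touching tips merge into one object and are counted once; at the
  default 2 % overlap budget this produces the slight negative bias and
  slope just below 1 visible in the agreement reports. No declumping
  (e.g. watershed) is attempted — the counting convention is one object,
  one shoot.
* A single global threshold assumes the paint/background contrast is
  spatially uniform; strong illumination gradients would require tiling
  or correction, which is out of scope.
* The descriptor set is 2-D and purely morphometric; no colour, texture
  or 3-D cues.
* Species-specific behaviour is emulated only through tip eccentricity
  profiles; real inter-species differences (leafage density, stem wall
  thickness) are richer than that.
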