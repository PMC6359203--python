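# Methods

## Problem setting

A colored point cloud of a plant (from structure-from-motion photogrammetry
or any RGB-D source) samples the canopy surface with per-point 8-bit sRGB
color. Two per-point quantities are derived from it: areal chlorophyll
content, via a color calibration, and local surface orientation, via plane
fitting. Day-indexed repeats of the same plant are then summarized into
per-leaf/per-region time series to track stress responses.

## Spatial calibration

Reconstructions carry arbitrary units and orientation. A reference box of
known edge lengths supplies picked point pairs `(a, b, known_cm)`; the scale
is the **unweighted arithmetic mean** of per-pair ratios known/model — simple
and unbiased for small, independent picking errors; no weighting scheme is
defensible without a noise model for the picks. If an edge known to be
vertical is supplied, the minimal (Rodrigues) rotation carrying it onto +z
defines the gravity frame; translation is left at zero because absolute bench
position is meaningless. The result is a similarity transform, so it
preserves all distance ratios exactly — the property the tests check on
random clouds. Re-applying a calibration to an already-calibrated cloud is an
error: double scaling is a silent unit corruption.

The calibrated frame convention is right-handed, z-up, units cm. All
downstream geometry (cube side, region radii, zenith) assumes it.

## Chlorophyll calibration

The normalized Red value r = R/(R+G+B) is computed from stored 8-bit values
as-is — no gamma linearization or white balancing, since the calibration is
fitted to the same color pipeline it is later applied to, any monotone
channel transform is absorbed by the regression so long as it is consistent
between calibration and mapping. r is undefined for pure black (R+G+B = 0);
such points are masked, never imputed.

The calibration regresses chlorophyll **on** r (ordinary least squares),
matching the predictive use; R² is the squared Pearson correlation of this
single-predictor fit. Reference chlorophyll comes from leaf punches: the
Porra (1989) equation for total chlorophyll a+b in buffered 80% acetone,
17.76·A₆₄₆.₆ + 7.34·A₆₆₃.₆ μg/mL, then areal normalization by
extract volume / punch area (both required config inputs, in mL and mm²).

Cross-validation is leave-one-out by default: with calibration sets of a few
dozen points LOOCV is deterministic and nearly unbiased. It is computed with
the hat-matrix identity (deleted residual = e_i/(1−h_ii)), which is
algebraically exact, and the test suite holds it equal to an explicit
n-refit loop to 1e-10. A seeded k-fold option exists for larger sets.

Mapping the curve over a cloud keeps out-of-range (negative) predictions and
flags them instead of clipping: clipped values would silently hide
extrapolation beyond the calibrated color range.

## Angle estimation

Neighborhoods are **axis-aligned cubes** with side L = 0.5 cm and closed
bounds (|p_k − c_k| ≤ L/2 per axis); the boundary convention matters when
points sit exactly on it, so it is part of the contract, and any spatial
index must reproduce the exhaustive-scan result exactly (the implementation
uses a k-d tree Chebyshev query, which does).

The plane fit is **orthogonal least squares** — the normal is the
least-variance eigenvector of the centered neighborhood covariance — rather
than a z-on-xy regression, which becomes ill-posed for steep leaves.
Normals are up-signed (n_z ≥ 0), so zenith ∈ [0°, 90°]; a fitted plane
cannot distinguish a leaf's upper from lower surface, so leaves known to
droop below the horizontal are handled afterwards by per-leaf `down` flags
that negate the signed zenith. Azimuth is measured counterclockwise from +x
in [0°, 360°); for zeniths under a configurable horizontal threshold
(default 1°) it is reported but flagged meaningless. Neighborhoods with
fewer than `min_points` (default 10 — enough to average sampling noise
without oversmoothing at ~400 points/cm²) or with degenerate geometry are
masked invalid, never extrapolated.

Numerical notes: degeneracy is declared when the second covariance
eigenvalue falls below 1e-12 of the largest (collinear/coincident points);
the normal's sign tie at n_z = 0 resolves to a positive first nonzero (x, y)
component; azimuth equivariance under z-rotation and exact recovery on
noiseless planes hold to 1e-6°.

## Monitoring

Per-leaf regions follow the field practice of tracking a few small areas
through time: the **centroid** (labeled point nearest the leaf mean) and the
**left/right edges** (labeled points at the extremes of the leaf's second
principal axis — the in-plane width axis), each pooled over a 0.25 cm radius
(the tracked spots are "small points"; their exact size is a free parameter).
Leaf labels are inputs; reconstructions on different days are independent,
so correspondence across days exists only at the level of labels and
regions, not points — a documented gap, not something the package infers.

Azimuth summaries use circular (vector) means and circular SDs throughout;
arithmetic means are wrong near the 0/360 wrap. Histograms use fixed-width
bins (defaults 1 chlorophyll unit, 5° for angles).

The between-day omnibus test is **Kruskal–Wallis**: per-point distributions
within a leaf are bounded and skewed, so a rank test is safer than ANOVA; a
Welch ANOVA option is provided. Caveat: points within a leaf are spatially
autocorrelated, so the effective sample size is far below the point count
and these p-values are descriptive, not strictly inferential.

## Synthetic data

The generator emulates what the pipeline needs to see, not photorealism:

* **Leaves** are elliptical patches (default 4 cm × 2 cm, 400 points/cm²)
  at specified zenith/azimuth, optionally bent by a parabolic fold across
  the short axis — the simplest family exercising within-leaf angle spread.
  Gaussian noise (default σ = 0.02 cm, a plausible reconstruction roughness
  at this scale) displaces points along the local analytic normal, whose
  exact per-point angles are recorded as ground truth.
* **Chlorophyll** is an affine field over leaf-local coordinates (default
  base 10, gradient 0.3 per cm along the long axis). Colors are produced by
  inverting the calibration line: channel totals are fixed at 400 with green
  pinned at 100, so red = round(r_n·400) realizes the target normalized Red
  to ±0.5/400 — the documented quantization floor of round-trip tests
  (chlorophyll error ≤ |slope|·0.00125, inside the generic 8-bit bound
  |slope|/765). Fields that would clip more than half the points are
  rejected with a diagnostic.
* **The design calibration line** is chl = −40·r_n + 22: negative slope
  (more chlorophyll → less red reflectance), chosen so the preset day-mean
  chlorophyll values (12.9 → 7.0, treated as dimensionless since the source
  scale is unspecified) map to normalized Red ≈ 0.23–0.38, comfortably
  inside the realizable band [0.1125, 0.6375]. Calibration samples draw
  r_n uniform on [0.2, 0.4] with Gaussian response noise sized so the
  *population* R² equals 0.81 at n = 30; a fitted R² then scatters within
  its sampling band (99% Monte-Carlo interval ≈ [0.64, 0.92]).
* **Stress scenarios** hold per-leaf anchor means per day (chlorophyll,
  zenith, azimuth) with linear interpolation between anchors; the `fig4`
  preset drives leaf 1 through chlorophyll 12.9/11.7/7.0, zenith
  23.7°/33.1°/33.9°, azimuth 88.6°/119.3°/156.9° on days 1/3/5, with two
  younger leaves changing mildly. Zeniths leaving [0°, 90°] are clamped
  with a warning.
* All randomness flows from one integer seed through spawned numpy
  generators; equal seeds give bit-identical clouds.

What this does **not** emulate: self-occlusion, reconstruction artifacts
(holes, ghost points, color bleeding), non-elliptic leaf shapes, specular
highlights, or illumination drift between days. Passing tests therefore
demonstrate correctness of the algorithms under known geometry and color
models, not robustness to real SfM pathologies.

## Problem sizes

Test and acceptance runs use leaves of 1–2 cm axes at 150–400 points/cm²
(hundreds to a few thousand points per leaf), 100 noiseless and 15 noisy
leaves for angle-recovery measurements, 50 random clouds (up to 10⁴ points)
for the neighborhood oracle, and the three-leaf five-day scenario
(~7,500 points/day) end to end — sizes at which every stage's behavior is
already asymptotic while a full run completes in seconds.

## Known limitations

* The calibration is camera- and illumination-specific; a curve fitted under
  one light does not transfer.
* Leaf labels must be supplied (or simulated); no segmentation is included.
* Cross-day correspondence is by label/region only.
* p-values ignore spatial autocorrelation (see above).
* PLY support covers vertex elements (ascii and binary little-endian) with
  scalar properties; meshes and list properties are out of scope.
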