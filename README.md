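# phytocloud

Chlorophyll and leaf-angle monitoring from colored 3D plant point clouds.

Structure-from-motion photogrammetry turns a handful of photos of a potted
plant into a colored 3D point cloud. `phytocloud` turns such clouds into
per-point physiological and structural maps for stress monitoring:

* **Chlorophyll content** — chlorophyll absorbs red light, so the
  *normalized Red value* r = R/(R+G+B) of a leaf point falls as its areal
  chlorophyll content rises. A linear calibration `chl = a·r + b` (μg/mm²)
  is fitted by ordinary least squares to points with wet-lab reference
  measurements (leaf punches extracted in 80% acetone, absorbances converted
  by the Porra 1989 equation `chl_a+b = 17.76·A₆₄₆.₆ + 7.34·A₆₆₃.₆` μg/mL),
  validated by leave-one-out cross-validation, and mapped over every point.
* **Leaf inclination and azimuth** — for each point, an orthogonal
  least-squares plane is fitted to the points inside an axis-aligned cube of
  side 0.5 cm centered on it. The zenith angle θ = arccos(n_z) of the
  up-signed plane normal is the leaf inclination angle (0° horizontal, 90°
  vertical); the azimuth φ = atan2(n_y, n_x) ∈ [0°, 360°) is the compass
  direction of its horizontal projection.
* **Metric scale** — reconstructions are unitless; a reference box of known
  edge lengths (13 cm × 12 cm × 9 cm) placed in the scene provides picked
  point pairs from which a similarity transform (scale, z-up rotation) is
  estimated.
* **Monitoring** — per-leaf histograms, per-region summaries (leaf centroid,
  left edge, right edge), tidy day-indexed series, and between-day
  Kruskal–Wallis tests track how chlorophyll and structure change under
  stress (e.g. progressive water deficit).

A synthetic-data module generates labeled leaf clouds with exact ground
truth (orientation, chlorophyll field, reference cube, multi-day stress
trajectories), so the full pipeline is testable without any scan data.

## Worked example

Simulate a five-day water-stress scenario (three elliptical leaves; leaf 1
is the old, bottom, downward-drooping leaf), then run the full pipeline —
calibrate, map chlorophyll, estimate angles, aggregate:

```bash
phytocloud simulate --scenario fig4 --seed 42 --outdir sim/
phytocloud run --clouds sim/day1.ply --clouds sim/day3.ply --clouds sim/day5.ply \
    --samples sim/calibration_samples.csv --labels sim/labels.json --outdir out/
```

`phytocloud calibrate --samples sim/calibration_samples.csv --cv loo` prints
the fitted calibration:

```
Chlorophyll calibration (OLS)
  chl = -40.82 * r_n +22.38  [ug/mm^2]
  R^2 = 0.8784   n = 30
  residual SD = 0.8836
  loo cross-validated MAE = 0.7763 ug/mm^2
```

i.e. the fitted line recovers the generator's design line (slope −40,
intercept 22) within sampling error at the simulated noise level, and R²
scatters around the population value 0.81 used by the generator.

`out/series.csv` is tidy (day, leaf, region, quantity, mean, sd, n); for
leaf 1's centroid region it shows the programmed stress response — mean
chlorophyll dropping 12.9 → 11.7 → 7.0 while the mean inclination angle
rises ≈ 23.7° → 33.1° → 33.9° and the azimuth drifts ≈ 88.6° → 119.3° →
156.9° as the leaf twists. `out/day*_annotated.ply` carry per-point
`chlorophyll`, `zenith`, `azimuth` and validity flags as extra vertex
properties, and `out/manifest.json` records the config, package version and
input checksums that reproduce the run.

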