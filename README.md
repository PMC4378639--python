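# laminametrics

Quantitative analysis of leaf-lamina shape, surface curvature and
cell-proliferation patterning, built around the measurements used to
characterise cup-shaped and crinkly *Arabidopsis* leaf mutants.

## The problem and who this is for

A wild-type leaf blade is flat; mutants can curve it into a cup (net
positive Gaussian curvature) or ruffle its margin (negative curvature).
Developmental biologists quantify this with a small set of operational
measurements rather than full differential geometry:

* **Planar morphometrics** of flattened laminae — length *L*, width *W*,
  perimeter *P*, area *A*, leaf index *L:W* — with the convention that
  cupped or crinkly leaves are cut open, flattened piecewise, and the
  freshly cut edges excluded from the perimeter.
* **The curvature proxy** `P/√A`, a scale-free statistic. For planar
  shapes it is bounded below by the isoperimetric value `2√π ≈ 3.545`
  (the disc); a cupped surface pulls it **below** the value its planform
  predicts, marginal over-growth pushes it **above**. The planform
  prediction comes from treating the leaf as a planar ellipse with
  semi-axes `a = L/2`, `b = W/2`:

  `P = 2π √((a² + b²)/2)`,  `A = π a b`,

  so the predicted `P/√A` depends only on the aspect ratio *L:W*.
* **Mitotic-arrest-front profiling** — the percentage of cells positive
  for a mitotic GUS reporter, counted in 200 × 100 µm fields tiled from
  midrib to margin inside the division/differentiation transition zone.
  A profile declining toward the margin (convex front) promotes cupping;
  one rising toward the margin (concave front) promotes crinkly margins.
* **Proliferation-zone dynamics** — the basal zone where cells still
  divide, measured as the distance from the lamina base to where the
  GUS-positive fraction beside the midrib drops to ~10%, regressed on
  total leaf length across a developmental series.
* **Growth kinetics** — leaf width sampled on alternate days, with the
  peak finite-difference rate as the summary statistic.
* **Cell-level statistics** — field-based epidermal cell size
  (field area / cells per field, ≥ 8 fields), derived cell counts
  (leaf area / mean cell size), and trichome branch-number frequencies.

Every input the pipeline consumes can be generated by the
`laminametrics.synthetic` module with known ground truth: elliptical
outlines with calibrated margin waviness, triangulated cap/saddle/flat
laminae, jittered hexagonal Voronoi cell lattices with Bernoulli GUS
status drawn from preset front-shape probability functions, logistic
growth series, linear zone-length series, and rendered stain images with
exact pixel masks for testing the segmentation stage.

## Worked example

```python
import math
import laminametrics as lm

# Null model: a flat elliptic leaf with the wild-type mean dimensions
m = lm.EllipseModel(a=12.8 / 2, b=9.0 / 2)
print("predicted P  =", round(lm.ellipse_predicted_perimeter(m), 2), "mm")
print("predicted A  =", round(lm.ellipse_area(m), 2), "mm^2")
print("predicted P/sqrt(A) =", round(lm.predicted_proxy_from_length_width(12.8, 9.0), 3))
print("measured  P/sqrt(A) =", round(lm.curvature_proxy(36.3, 90.3), 3))

# Intrinsic metrics on a curved lamina: a hemisphere reads as cupped
hemi = lm.mesh_metrics(lm.synthetic.gen_surface(
    lm.SurfaceSpec("spherical_cap", 1.0, curvature_param=math.pi / 2,
                   mesh_resolution=0.03)))
print("hemisphere proxy =", round(hemi.proxy, 3), "->", hemi.curvature_class)

# Growth kinetics: noiseless wild-type logistic sampled on alternate days
rates = lm.growth_rates(lm.synthetic.gen_growth_series(
    lm.GrowthSpec(w_max=9.0, r_max=0.5, t_mid=8.0)))
print("peak growth rate =", round(rates.peak_rate, 3), "mm/day on day",
      int(rates.peak_day))

# Proliferation-zone dynamics on a synthetic wild-type-like series
slope, r2 = lm.zone_slope(lm.synthetic.gen_zone_series(
    lm.synthetic.ZONE_PRESETS["col0"]))
print("zone slope = %.3f mm/mm (R^2 = %.2f)" % (slope, r2))
```

prints

```
predicted P  = 34.76 mm
predicted A  = 90.48 mm^2
predicted P/sqrt(A) = 3.654
measured  P/sqrt(A) = 3.82
hemisphere proxy = 2.507 -> positive
peak growth rate = 0.492 mm/day on day 8
zone slope = -0.356 mm/mm (R^2 = 0.84)
```

Reading the output: the wild-type leaf's measured proxy (3.8) sits
slightly above its elliptic prediction (~3.65, from margin irregularity),
while a cupped surface such as the hemisphere falls well below the flat
floor `2√π ≈ 3.545` — the signature of positive Gaussian curvature. The
peak width-growth rate recovers the 0.5 mm/day generating value within
the 2-day sampling discretisation, and the zone regression recovers the
−0.37 mm/mm generating slope within its sampling error.

A command-line umbrella covers the same surface
(`laminametrics synth|measure|predict|mesh-metrics|profile|zone-slope|growth|segment|run`);
`laminametrics run --out run_out` executes the whole
synth → measure → profile → summarize pipeline and writes TSV tables
plus a JSON run log.

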