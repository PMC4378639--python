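# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The curvature proxy and its null model

The central statistic is `P/√A`: boundary perimeter over the square root
of surface area. It is scale-free, and for planar shapes it obeys the
isoperimetric inequality `P/√A ≥ 2√π`, with equality only for the disc.
On a curved lamina the statistic is computed *intrinsically*: surface
area is the sum of triangle areas of the mesh and perimeter the summed
length of boundary edges. Because both quantities are intrinsic, this
equals what the physical cut-and-flatten measurement yields when freshly
cut edges are excluded — no flattening or parameterisation step is
implemented, and none is needed for the statistic.

Interpretation uses two references:

* the **flat-disc floor** `2√π ≈ 3.545`. For a spherical cap of
  half-angle θ the proxy is analytically `√(2π(1+cos θ))` — strictly
  decreasing in θ, always below the floor (hemisphere: `√(2π) ≈ 2.507`);
  a saddle `z = k·x·y` rises above the floor, monotonically in |k|.
  The mesh metrics reproduce both closed forms within 1% at the default
  resolution, and `curvature_class` labels a mesh positive/flat/negative
  with a ±2% band around the floor, chosen to exceed discretisation
  error at the default 0.03–0.05 mm edge lengths.
* the **planar-ellipse null model** `P = 2π√((a²+b²)/2)`, `A = πab` with
  `a = L/2`, `b = W/2`. The perimeter form is deliberately the simple
  quadratic-mean approximation (error < 1% versus Ramanujan's series for
  leaf-like aspect ratios, documented in the tests); its prediction
  depends only on L:W, isolating the planform contribution from the
  curvature contribution. Both aspect ratios of interest (1.4 and 0.9)
  predict `P/√A ≈ 3.6` at one decimal, so measured deviations from ~3.6
  in either genotype are not planform effects.

Known limitation (inherited from the statistic itself): `P/√A` is a
*global* proxy; it confounds the spatial distribution of Gaussian
curvature with planform irregularity. No pointwise curvature estimator
(angle deficit etc.) is provided, and no correction for heterogeneous
curvature exists.

## Planar measurement conventions

* **Length axis**: the major principal axis of the outline, computed by
  PCA of equal-arc-length boundary resamples (1024 points) — operator
  independent, exactly rotation equivariant, and insensitive to how
  densely the boundary was digitised. For near-isotropic outlines the
  axis is unidentifiable; the tie-break (relative eigenvalue gap below
  1e-6) falls back to the x axis. Generated outlines carry their known
  proximo-distal axis, and `measure_outline(axis="x")` uses it — this
  matters for rounder-than-long mutant leaves, where the principal axis
  is the medio-lateral one.
* **Width**: the maximal extent orthogonal to the length axis (a single
  maximal chord, matching ruler/thread practice, not a mean width).
* **Perimeter under cutting**: each flattened piece is measured with its
  cut edges excluded and the pieces summed. This conserves the intact
  margin length exactly for any partition (property-tested on random
  chord partitions).
* **Serration smoothing**: an optional moving average of boundary radius
  ("through the middle of the serrations"); off by default because the
  focal genotypes' mature fifth leaves are unserrated.
* **Growth rates**: centred finite differences on the sampling grid, no
  smoothing by default (peak rates are reported raw from 2-day
  sampling). With alternate-day sampling of a logistic the peak rate is
  recovered within ~2% (0.492 vs 0.5 mm/day) — well inside the 5%
  discretisation allowance.

## Synthetic-data generators (the study conditions)

The generators' defaults encode the conditions of the measurements they
emulate; they are fixed, not tuning knobs.

* **Outlines**: parametric ellipse (the null model's own family) plus
  smooth radial waviness over wavenumbers 2–16 with 1/k amplitudes —
  margin irregularity without serration teeth. The cohort presets use
  between-leaf SDs equal to the published SEM·√n and margin roughness
  0.12, calibrated once so that a wild-type cohort's measured group
  `P/√A` averages the published 3.8 — i.e. the generator reproduces the
  documented gap between measured (3.8) and ellipse-predicted (~3.65)
  values that real, imperfectly elliptic margins show. A planar outline
  cannot reproduce the cup-shaped mutant's measured 3.2, which lies
  *below* the planar floor for its planform: that deficit is precisely
  the surface-curvature signal, and it is represented by the curved-mesh
  generator instead. Waviness inflates measured extents by ~2% at the
  calibrated roughness, a known artefact small against the cohort SDs.
* **Surfaces**: hexagonal-lattice points with an exact boundary ring,
  Delaunay-triangulated; the spherical cap is built on an
  azimuthal-equidistant chart so every vertex lies exactly on the
  sphere. Single boundary loop by construction.
* **Cell lattices**: jittered hexagonal Voronoi (jitter SD 0.18 of the
  lattice spacing), site density exactly one cell per target area,
  bounded by mirror reflection and clipped to the patch — space-filling,
  isotropic, mean cell area within 10% of target. Transition-zone bands
  for front profiling use 1.0 × 0.1 mm patches of ~160 µm² cells
  (young-leaf scale), giving 100–150 cells per 200 × 100 µm field.
* **Front presets** (`p(x)`, GUS-positive probability over the
  normalized midrib→margin coordinate): wild-type-like linear
  0.25 → 0.10; cup-mutant-like piecewise-linear 0.27 at the midrib
  rising to a broad 0.40 plateau over x ∈ [0.2, 0.35] ("slightly towards
  the margin") and falling to 0.15 at the margin; crinkly-mutant-like
  monotone increasing 0.10 → 0.30. The coordinate is anchored at the
  *centres of the first and last counting fields* — the x axis on which
  the source profiles are plotted — so binned recovery of a linear
  profile is unbiased at the plotted positions; cells in the outer
  half-fields use the profile's continuous linear extension, clipped to
  [0, 1]. Assignment is independent Bernoulli per cell at its centroid.
* **Growth**: logistic `w(t) = w_max / (1 + exp(−4 r_max (t − t_mid) /
  w_max))` — parameterised directly by the peak rate `r_max`, because
  peak rates are what is reported. Presets: wild type `w_max = 9 mm`,
  `r_max = 0.5 mm/day`, `t_mid = day 8`; mutant `w_max = 16.2 mm`,
  `r_max = 1.0 mm/day` (twice wild type), `t_mid = day 10` (wider, grows
  longer). Measurement noise SD 0.2 mm (thread/ruler scale; the
  wire graduation was 0.25 mm).
* **Zone series**: `zone = intercept + slope·L + ε`, leaf lengths
  uniform on 1–3 mm, slopes −0.37 (wild type) and +0.43 (mutant, the
  figure-caption value; the running text's +0.38 is recorded as a
  discrepancy). Noise SDs (0.15 / 0.14 mm) are derived in closed form
  from `R² = s²Var(L)/(s²Var(L)+σ²)` at the published R² (0.67 / 0.76) —
  the calibration is analytic, not fitted. Intercepts (1.25 / 0.20 mm)
  keep the line inside [0, L] over the length range; draws that still
  fall outside are clipped to the boundary and flagged (~2% of wild-type
  draws), a bias small against the OLS sampling error. At n = 20 the
  OLS slope SE is ≈ 0.06, so single-series recovery lands within ±0.10
  of the generating slope for ~90% of seeds — the inherent precision of
  the published design, not a property of this implementation.
* **Stain renders**: dark cell walls, pale unstained interiors, indigo
  stained interiors, each interior shrunk by 1.5 px so neighbouring
  stained cells stay 8-connectivity-separated; the ground-truth mask is
  exactly the stained pixels drawn. Optional seeded Gaussian noise as a
  fraction of the 0–255 range.

## Arrest-front profiling and zone dynamics

Fields tile midrib→margin without overlap; a cell belongs to the field
containing its centroid; a trailing partial field is kept if ≥ 50% of a
field width, else merged. Per-leaf profiles are binned first and then
averaged field-by-field across leaves (11 wild-type-like / 5
mutant-like), with pooled binomial SEs.

Front classification is rule-based where the source classifies by eye:
with `c` the mean fraction over the midrib-side third of fields, `m` the
marginal third, and `p*` the argmax field — concave if `m − c > δ`,
convex if `c − m > δ` (upgraded to strong-convex-with-midrib-dip when
`p*` is interior and exceeds the first field by > δ), flat otherwise.
δ = 0.05 ≈ twice the binomial SE at 150 cells/field.

Zone length slides a 100 µm window (matching the field height; no value
is prescribed) up the 200 µm midrib-adjacent column in 10 µm steps and
returns the most-proximal window where the GUS fraction first falls to
the 10% threshold — a threshold that is explicitly operational, not
biological. Because the fraction declines tipward, zone length is
monotone non-increasing in the threshold. Whether fractions count all
epidermal cells or pavement cells only is left to the caller's cell
table; the synthetic lattices model pavement cells only.

## Segmentation stage

Default classifier: a stain-discriminant channel `B − (R+G)/2` (large
for the indigo stain, ≈ 0 for the colour-neutral walls and pale
background), lightly smoothed (Gaussian σ = 0.8 px) and thresholded by
Otsu's bimodal criterion. An alternative nearest-mean classifier is
trained from labelled pixel strokes, with the background class modelled
by two colour means (pale interiors and dark walls are separate modes).
Objects are 8-connected components with area ≥ `min_area` (default
usage: 25% of the expected cell area, which removes noise specks).
Touching stained cells are *not* split by default — rendered lattices
keep stained interiors wall-separated, and distance-transform watershed
(available as `split_touching=True`) risks over-splitting concave
cells. On noiseless renders the detected count equals the true stained
cell count exactly; at noise SD 10% of dynamic range the count error
stays below 5%, and automated per-field fractions agree with
ground-truth counts within 0.05 — the manual-vs-automatic agreement
level the original workflow reports. Everything is deterministic given
the image and configuration.

## Group statistics

Group `P/√A` is reported both as the mean of per-leaf ratios and as the
ratio of mean perimeter to √(mean area); the latter is the
published-table-comparable convention (36.3/√90.3 = 3.82 → 3.8).
SEM = SD/√n; single-leaf groups report SEM 0 with a flag. The t-test is
two-sided pooled-variance Student by default (Welch available — the
source names only "Student's t-test"); p-values are reported raw, with
no multiple-testing correction, and starred at 0.05/0.01/0.001.

## What the synthetic data do and do not show

The generators reproduce the *statistical structure* of the
measurements: sampling grids, counting-field sizes, binomial counting
noise, published slopes, rates, fractions and fit quality. They do not
simulate growth mechanics, the developmental origin of curvature,
serrations, vasculature, staining chemistry or optical artefacts of
real micrographs. Passing tests therefore demonstrate that the
*procedures* recover known parameters under realistic noise — not that
the procedures are robust to every property of real images or real
leaf-shape variation.

## Problem sizes

Defaults keep the full test suite and the acceptance script fast on one
CPU: front-profile simulations use 1.0 × 0.1 mm bands (5 fields,
~600 cells per leaf; 11 or 5 leaves), zone series n = 20, meshes at
0.03–0.05 mm resolution (~3–5 k triangles), renders at 1 µm/px
(1000 × 100 px).
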