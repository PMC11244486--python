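# Methods

This note documents the models, the tunable parameters and their defaults,
the numerical choices, and what the synthetic tests do and do not show about
real scans.

## Input model and preprocessing

The unit of analysis is one registered, denoised TLS cloud of a single rice
plant, in meters, Z up, base near z = 0. Multi-scan registration, removal of
pots/soil/targets and any manual cropping are assumed done upstream (they
belong to the scanner vendor's workflow); the package starts at the exported
cloud.

Every extraction begins with:

1. **Base normalization** — translate so min z = 0. This defines the height
   reference and the slice coordinates. An optional `--crop-below` drops
   residual root/soil points first.
2. **Statistical outlier removal (SOR)** — keep points whose mean distance to
   their k nearest neighbors is ≤ μ + r·σ of that statistic over the cloud.
   Defaults k = 20, r = 2.0, the conventional values of the point-cloud
   ecosystem; recorded in `params_used`. SOR is a global-density filter: on
   perfectly homogeneous data it is the identity in the interior, but points
   on the *boundary* of a bounded sample genuinely have sparser neighborhoods,
   so for large k a few edge points can cross the threshold. That is a
   property of the statistic, not a bug.

Slices are half-open intervals [z_min, z_max), so adjacent slices partition
the cloud and boundary points are never double-counted.

## Stepped radius search (crown radius, stem perimeter)

The search center is the horizontal centroid of the stem cross-section
[3 cm, 4 cm) above the base — stems are conventionally measured ~3 cm above
the root, and using the stem centroid as the canopy center assumes the plant
was scanned upright. A closed ball around the center grows from `r_start` in
steps of `step` until it encloses all projected points. Parameters:

| parameter | crown | stem | why |
|---|---|---|---|
| step | 0.02 m | 0.005 m | 2 cm is the canonical step at canopy scale; on a ~3–6 cm stem tuft a 2 cm step would dominate the error, so the stem uses 5 mm |
| r_start | = step | = step | first probe after one step |
| r_max | 2.0 m | 2.0 m | sanity bound; exceeding it raises with the true max distance |

The estimate always rounds *up*: `R* ∈ [d_max, d_max + step)`. Under additive
range noise the quantized quantity is the noisy maximum distance — an extreme
value that sits a few noise σ above the noiseless truth — so recovery tests
allow `truth ≤ R* ≤ truth + step + 5σ`. The membership test is inclusive
(d ≤ R), which makes termination well-defined when the farthest point falls
exactly on a probe radius.

The stem perimeter treats the enclosing radius as a circle radius (`2πR`).
This measures the girth of the whole tiller *tuft*, not of a single culm —
the same convention a tape measure around the stem bundle produces.

## Alpha-shape surface area

`alpha_shape_mesh` implements the classical ball definition: a Delaunay
triangle is a boundary facet iff an empty ball of radius α passes through its
three vertices. The two candidate ball centers sit at `c ± n̂·√(α² − r_c²)`
from the triangle circumcenter; a facet is kept when the nearest cloud point
to either center lies at distance ≈ α (the face's own vertices are at exactly
α; anything strictly closer is inside the ball, anything farther marks a
numerically degenerate circumcenter). Relative tolerance 1e-9.

Numerical notes:

- **α = ∞ is the convex hull**, implemented exactly via the hull facets.
  At large *finite* α the classical definition genuinely admits extra
  near-hull "pocket" facets (a ball of radius α deviates from a half-space by
  a sagitta ρ²/2α, so facets slightly inside the hull can still own an empty
  ball); the limit is therefore special-cased rather than approximated.
- **Exactly co-spherical inputs** (analytic sphere samples) are degenerate
  for Delaunay; qhull's default facet merging handles them correctly but
  slowly (~2 min at 20k points). Joggling (`qhull_options="QJ"`) is faster
  but resolves the degeneracy into interior chord faces whose inward balls
  are empty in a hollow sample, inflating the area; default options are used.
- **Hollow thin structures**: for a surface sampled with range noise, the
  mesh wraps the noisy slab. Points in the slab interior are legitimately
  not boundary vertices, and the reconstructed surface follows the noise
  roughness. Both effects make the alpha-shape area of a noisy zero-thickness
  ribbon sample systematically larger than the smooth parametric area (a
  factor of ~2–5 at σ = 1 mm, α ≈ 4 mm). The package reports what the
  reconstruction measures; no claim is made that this equals one-sided leaf
  area.

`auto_alpha` sweeps α = 0.0040 : 0.0005 : 2.0 (the published grid) and
returns the smallest α whose mesh is non-empty and whose largest connected
component holds ≥ 99% of the mesh vertices. The selection rule is this
package's design: it rejects fragmented meshes (holes splitting the surface,
or two separate objects never merging) while tolerating the isolated
micro-islands residual noise always produces. Total-input-point coverage is
deliberately *not* required — interior slab points can never be boundary
vertices, so a coverage criterion is unattainable on noisy data. One
Delaunay triangulation and one kd-tree are shared across the sweep, so only
the per-facet ball test repeats.

Volume is the 3D convex hull (`scipy.spatial.ConvexHull`), per the trait's
definition; it brackets the canopy envelope and ignores concavities by
construction.

## Projected leaf area

`PLA = 100 · projected_area / mbr_area`, where `projected_area` counts
distinct occupied cells of an axis-aligned grid (default 1 cm, the scale of
TLS point spacing) anchored at the projection's (min x, min y) — anchoring
makes the statistic translation-invariant — and `mbr_area` is the
minimum-area rotated rectangle of the projection (shapely's
rotating-calipers implementation, cross-checked in tests against exhaustive
hull-edge search). Points on the grid's upper boundary are clamped into the
last cell. Because cells overhang the rectangle, the ratio can exceed 100%;
it is clamped and the raw value kept (`pla_raw`). The rectangle area is
floored at one cell to keep the ratio finite for degenerate clouds.

## Tiller counting

Clustering runs on the 3D coordinates of the slice [3 cm, 6 cm) above the
base — above root clutter, below leaf emergence, thick enough that each culm
contributes a dense vertical run — after SOR. The metric is mutual
reachability `d_k(p,q) = max(c_k(p), c_k(q), d(p,q))` with core distance
`c_k(p)` = distance to the k-th neighbor; `mutual_reachability_matrix`
exposes it directly and is checked against per-pair brute force.

Parameters and their reasoning:

- `min_cluster_size` = max(10, round(0.2 · N_slice / 25)): scales with slice
  density assuming at most ~25 tillers, floored at 10.
- `min_samples` = 5. Larger values (e.g. 10) smooth the core-distance field
  over the density valley between adjacent culm tubes and merge neighbors;
  at 5 the exact-recovery rate on mock slices at 15 mm separation is 50/50
  versus 37/50 at 10.
- `merge_radius` = 6 mm: clusters whose horizontal centroids are closer than
  this are merged before counting. Rationale: a tiller is a distinct stem
  position in the XY plane. Excess-of-mass extraction can never select the
  hierarchy root, so an *isolated* culm is otherwise returned as 2–3
  vertically stacked sub-segments at the same XY location; 6 mm (≈ one culm
  diameter) merges those while true neighbors ≥ 1.2 cm apart are untouched.
  (`cluster_selection_epsilon` would express the same idea inside HDBSCAN
  but is unusable in the installed scikit-learn.)
- If the first pass labels everything noise, a single-cluster pass is
  accepted only when the cluster holds ≥ 50% of the slice: a one-tiller
  plant counts 1, a diffuse scatter with no density structure counts 0.

Separation limits, measured on mock slices (3 mm tube radius, 1 mm noise,
per-axis point spread ≈ 2.3 mm): exact recovery is ≥ 95% for culm-axis
separations ≥ ~6× the spread (15 mm), degrades near 5×, and pairs fused
below ~2 mm are counted as one (an acknowledged merge, bounded in tests).

## Evaluation statistics

`RMSE = √(Σ(x̂ᵢ−xᵢ)²/n)`; `RRMSE = 100·RMSE/x̄` with x̄ the mean of the
**measured** values; `R²` is the coefficient of determination of the
ordinary linear fit of extracted on measured (equivalently the squared
Pearson correlation). A legacy variant `1 − Σ(x̂ᵢ−x̄)²/Σ(xᵢ−x̄)²` exists
behind `formula="legacy"` for comparison only: it is not residual-based, can
exceed 1 and misses perfect non-identity fits. RRMSE difference bands are
left-closed at 10/20/30%.

## Synthetic plants and what the tests show

`generate_plant` builds a parametric plant and samples its surfaces:

- **Culms**: 5–25 thin tubes (radius 3 mm) leaning outward along quadratic
  centerlines from a basal crown; base positions on a jittered sunflower
  (golden-angle) layout inside a ≤ 5 cm disk — deterministic, near-densest
  packing, raising `SpecError` when the requested minimum separation is
  infeasible. One culm reaches the spec height exactly.
- **Leaves**: zero-thickness tapering ribbons arching from mid-culm out to
  the canopy radius and drooping, sampled on both faces; one designated leaf
  reaches exactly `crown_radius`.
- **Basal crown**: a squat cylinder (z ≤ 1.2 cm) joining the culm bases, as
  the root crown does; it also makes the geometry one connected component.
- **Sampling**: surfaces at ≈ `point_spacing` (default 2 mm) with
  sub-spacing jitter, then isotropic Gaussian range noise σ = 1 mm — inside
  the 0.1–1.3 mm error band of the reference scanner class. Optional
  uniform outliers in a 3× inflated bounding sphere.

Randomness splits into a geometry stream and a sampling stream derived from
the spec seed: ground truth is computed from the noiseless geometry (dense
deterministic resampling for crown radius, hull volume and PLA; analytic
integration for surface area; culm-axis geometry for the stem perimeter), so
changing only the noise level leaves the truth unchanged, and the same spec
reproduces the cloud bit-for-bit.

The study cohort (`study_spec`, used by the fixture suite and the acceptance
script) varies tiller count 8–18, height 0.7–1.1 m, crown radius
0.25–0.35 m, and scales the basal radius with tiller count so stem girth
genuinely differs between plants.

What the generator does **not** emulate: occlusion and self-shadowing
(real two-sided scans are incomplete — robustness is tested with 30% random
dropout instead), leaf twist and curl, panicles, wind motion, registration
error structure, and intensity. Passing the synthetic recovery tests
therefore demonstrates the correctness and stability of the estimators under
realistic density and noise, not field accuracy on real plants — the
published field validation of this family of methods reports
centimeter-level RMSE and RRMSE bands from "none" to "small" on real scans,
and those numbers cannot be reproduced without the original plants.

## Problem sizes and determinism

Default problem sizes: study plants sample ~50–90k points at 2.5 mm spacing;
the recovery cohort is 20 plants; the sphere check uses 20k points; mock
clustering slices are ~1k points. These sizes put the whole test suite and
the acceptance script at a few minutes on one CPU while keeping every
statistic stable.

All pipelines are deterministic for fixed inputs and seeds (HDBSCAN and all
geometry are deterministic; the only randomness is the seeded generator), so
`synth → extract → eval` reproduces byte-identical outputs, which a test
asserts.

## Known limitations

- Crown radius assumes the stem centroid is the canopy center; leaning
  plants bias it upward.
- The stem perimeter measures the tiller-bundle girth at a fixed height; it
  is sensitive to the chosen slice when culms splay.
- Alpha-shape area on noisy thin canopies overestimates smooth-surface area
  (see above); comparisons are meaningful between scans processed with the
  same α and noise level, not against destructively measured leaf area.
- Tiller counts merge culms closer than ~2 mm at the slice height and
  under-count when separation approaches ~5× the point spread.
- PLA depends on the grid size; 1 cm is reported with the result so values
  are comparable across runs.
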