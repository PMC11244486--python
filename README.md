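# tillerscan

Automated phenotypic trait extraction for single rice plants from
terrestrial-laser-scan (TLS) point clouds.

A tripod LiDAR scan of one rice plant — registered, cleaned of non-plant
objects and exported as a point cloud in meters — contains almost every
architectural trait a breeder measures by hand. `tillerscan` computes seven
of them from a single cloud:

| trait | method |
|---|---|
| crown radius | stepped radius neighborhood search from the stem centroid |
| stem perimeter | enclosing-circle radius of a stem cross-section, × 2π |
| plant height | vertical extent above the normalized base |
| surface area | alpha-shape surface reconstruction |
| volume | 3D convex hull |
| projected leaf area (PLA) | grid occupancy ÷ minimum bounding rectangle |
| tiller number | HDBSCAN density clustering of a low stem slice |

It also ships the accuracy statistics used to validate extractions against
manual measurements (R², RMSE, RRMSE with difference bands), and a synthetic
plant generator with exact ground truth, so the full pipeline is testable
without any scan data.

## The algorithms in brief

**Stepped radius search.** Project the cloud onto the XY plane, take the
centroid `Z(x̄, ȳ)` of a stem cross-section as center, and grow a closed ball
in fixed steps `R ∈ {r₀, r₀+s, r₀+2s, …}` until the number of enclosed points
`k` equals the projection size `n`; the first such `R` is the crown radius
(step 2 cm) or the stem-section radius (step 5 mm), and the stem perimeter is
`2πR`. The answer satisfies `d_max ≤ R < d_max + s`.

**Alpha shape.** `α` is the radius in meters of a probe ball. A Delaunay
triangle belongs to the boundary mesh when a ball of radius `α` through its
three vertices contains no other point; `α = ∞` gives the convex hull.
Surface area is the sum of boundary-triangle areas. `auto_alpha` sweeps
`α = 0.0040, 0.0045, …` and returns the smallest value whose mesh is
essentially one connected surface.

**PLA.** `PLA = 100 · (occupied cells · cell²) / MBR area`, with a 1 cm
axis-aligned grid anchored at the projection's min corner and the
minimum-area rotated rectangle of the projection (clamped at 100%).

**Tiller number.** Slice `[3 cm, 6 cm)` above the base, statistically filter,
and cluster in 3D with HDBSCAN on the mutual-reachability metric
`d_k(p,q) = max(c_k(p), c_k(q), d(p,q))`; clusters sharing a horizontal stem
position are merged; the cluster count is the tiller number.

**Evaluation.** `RMSE = √(Σ(x̂ᵢ−xᵢ)²/n)`, `RRMSE = 100·RMSE/x̄` (mean of the
measured values), `R²` of the linear fit of extracted on measured. RRMSE
bands: <10% no difference, 10–20% small, 20–30% moderate, ≥30% large.

## Worked example

Generate three synthetic plants with known ground truth, extract all seven
traits, and compare:

```bash
tillerscan synth --plants 3 --seed 42 --out demo --point-spacing 0.003
tillerscan extract --input demo/plant_00.pcd --input demo/plant_01.pcd \
                   --input demo/plant_02.pcd --out demo/results.json
tillerscan eval --manifest demo/manifest.csv --results demo/results.json
```

prints

```
         trait  n     r2    rmse  rrmse_pct category
  crown_radius  3 0.9755 0.01776       5.73     none
stem_perimeter  3 0.9533 0.02980      10.45    small
  plant_height  3 0.9999 0.00225       0.24     none
  surface_area  3 1.0000 0.11178      33.51    large
        volume  3 0.9997 0.00095       1.11     none
           pla  3 0.9998 1.93736       5.94     none
  tiller_count  3 1.0000 0.00000       0.00     none
```

Reading the table: height is recovered to ~2 mm; the crown radius RMSE
(1.8 cm) is the 2 cm search-step quantization; the stem perimeter carries the
same quantization relative to a much smaller quantity, so its relative error
is the largest of the length traits — the behavior this estimator is known
for. Tiller counts are exact on all three plants. The surface-area row
compares the alpha-shape area of the *noisy sampled* cloud against the area
of the *smooth parametric* surfaces; range noise makes the reconstruction
rough, so the reconstructed area is systematically larger (see
`docs/methods.md`).

The first record of `demo/results.json`:

```
{'crown_radius_m': 0.36, 'stem_perimeter_m': 0.2827, 'plant_height_m': 0.8781,
 'surface_area_m2': 0.2816, 'volume_m3': 0.0813, 'pla_pct': 28.59,
 'tiller_count': 8}
```

Every record embeds `params_used` (slice bounds, steps, alpha, grid size, SOR
and clustering parameters), so any number can be re-derived exactly.

### Result schema

JSON keys per plant: `crown_radius_m`, `stem_perimeter_m`, `plant_height_m`,
`surface_area_m2`, `volume_m3`, `pla_pct`, `tiller_count`, `params_used`,
`source`. The CSV form has one row per plant with the same columns. The
fixture manifest written by `synth` has columns `file`, `tiller_count`,
`height_m`, `crown_radius_m`, `stem_perimeter_m`, `surface_area_m2`,
`volume_m3`, `pla_pct`, `seed`.

### Library use

```python
import tillerscan as ts

cloud = ts.read_point_cloud("plant.pcd")          # or .ply / .xyz
result = ts.extract_phenotypes(cloud)             # all seven traits
result = ts.extract_phenotypes(cloud, traits=ts.BASIC_TRAITS)  # skip meshing
```

Input formats: PCD (ASCII and uncompressed binary), PLY (ASCII and binary
little-endian), whitespace XYZ text. Coordinates are meters, Z up, plant base
near z = 0; `--unit-scale 0.001` converts millimeter scans at read time.

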