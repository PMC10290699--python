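# mycomap

Landscape-scale mapping of soil fungal communities from grid-sampled
metabarcoding surveys.

Soil fungi — ectomycorrhizal symbionts, saprotrophs, pathogens — are
routinely censused by ITS metabarcoding of soil cores, but the tabular
output (reads per taxon per sample) says nothing about *where* on the
landscape a guild is abundant. `mycomap` turns a georeferenced
sample-by-group abundance table from a regular sampling grid into
continuous distribution maps, and quantifies whether those maps can be
trusted:

- **Spatial autocorrelation** — global Moran's I with binary rook
  contiguity weights over the sampling lattice,

  I = n ΣᵢΣⱼ wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / [ (ΣᵢΣⱼ wᵢⱼ) Σᵢ (xᵢ − x̄)² ],

  with significance from a Monte Carlo permutation test (values shuffled
  over positions, pseudo-p = (1 + b)/(1 + m)).
- **Interpolation** — three raster interpolators: inverse distance
  weighting (IDW, power 2), ordinary kriging with automatic variogram
  fitting (Matheron estimator, weighted least squares over spherical /
  exponential / gaussian models, best r² wins, moving neighborhood), and
  multilevel B-spline approximation (MBA: hierarchy of cubic B-spline
  control lattices, each level fitting the previous level's residuals).
- **Validation** — repeated 80/20 holdout with RMSE =
  √(Σ(x̂ᵢ − xᵢ)²/n) at the held-out samples.
- **Stratification** — exact 1-D k-means (k = 2, 3) turning a map into
  low/medium/high abundance strata.
- **Reduced sampling effort (RSE)** — re-mapping from regular 1/2, 1/4
  and 1/9 subgrids and differencing against the full-data map
  (mean, SD and sum of squares of the difference raster).
- **Community tables** — rarefaction (subsampling without replacement to
  a common depth), OTU→taxon/guild aggregation, OTU richness, and
  hierarchically clustered Spearman correlation matrices between groups.
- **Synthetic surveys** — Gaussian-random-field landscapes sampled on a
  9 × 10 lattice at 100-m spacing with 5 failed samples, plus multinomial
  OTU count tables, so the full workflow is testable without sequencing
  data.

Everything is planar: supply projected coordinates (or accept
degree-space distances). Rasters are read and written as ESRI ASCII
grids or single-band float64 GeoTIFFs.

## Worked example

```python
from mycomap import (InterpolationConfig, build_rook_weights, holdout_validate,
                     island_points, moran_permutation_test)

pts, truth = island_points(seed=7)        # 90 grid samples, 5 failed
sub = pts.subset(pts.usable("abundance"))

w = build_rook_weights(sub)
res = moran_permutation_test(sub.attributes["abundance"], w, n_perm=999, seed=1)
print(f"I = {res.I:.3f}, p = {res.p:.4f}")

for method in ("idw", "kriging", "bspline"):
    cfg = InterpolationConfig(method=method, cell_size=50.0)
    rep = holdout_validate(pts, "abundance", cfg, n_reps=25, seed=3)
    print(f"{method}: mean holdout RMSE = {rep.mean_rmse:.3f}")
```

prints

```
I = 0.433, p = 0.0010
idw: mean holdout RMSE = 0.971
kriging: mean holdout RMSE = 0.947
bspline: mean holdout RMSE = 0.978
```

Moran's I of 0.433 with p = 0.001 says neighboring samples carry
similar abundances — the field is spatially structured at the 100-m
scale, so mapping is meaningful. The holdout RMSE ranks the
interpolators on this autocorrelated field: kriging predicts held-out
samples best, the exact-fit B-spline worst (it also reproduces the
sampling noise). On unstructured fields the ranking flips toward IDW.

The `examples/` directory has one narrative script per capability
(simulation, Moran's I, mapping, validation + stratification, reduced
sampling effort, community tables); each prints what it computes and
what the numbers mean.

## Command line

A thin CLI wraps the library:

```
mycomap simulate --seed 7 --out-dir survey/
mycomap moran --points survey/points.csv --spacing 100 --n-perm 999
mycomap interpolate --points survey/points.csv --column abundance \
        --method kriging --cell-size 20 --out map.tif
mycomap validate --points survey/points.csv --column abundance \
        --method idw --cell-size 50 --n-reps 100
mycomap stratify --raster map.tif -k 3 --out strata.tif
mycomap rse --points survey/points.csv --column abundance --spacing 100 \
        --method bspline --cell-size 20 --out-dir rse/
mycomap run --points survey/points.csv --columns abundance --spacing 100 \
        --cell-size 20 --out-dir results/
```

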