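# Methods

This note documents the statistical machinery behind `mycomap`, the
defaults it ships with and why, what the synthetic data emulate, and the
numerical choices a user or reviewer might want to audit.

## Data model and coordinate conventions

A survey is a `PointSampleSet`: unique sample ids, planar (x, y)
coordinates, and named nonnegative abundance attributes. All distances
are Euclidean in coordinate units; the package does no geodesy, so
users should supply projected coordinates (metres) or accept
degree-space distances. Samples that yielded no data ("failed" samples
— a routine occurrence in soil metabarcoding, e.g. failed DNA
extraction or sequencing) stay in the table with empty attribute cells
and are excluded from every statistic, weight matrix and interpolation.

Rasters are square-celled, north-up, row-major and cell-center
registered; `GridSpec.from_points` defaults to the samples' bounding
box padded by one cell. Point sampling of a raster uses the
nearest-cell rule (the value of the containing cell, no bilinear
smoothing), matching common GIS point-sampling tools. File formats are
ESRI ASCII grid and single-band float64 GeoTIFF (georeferencing via the
ModelPixelScale/ModelTiepoint tags, nodata via the GDAL tag); both
round-trip bit-identically.

`infer_grid_index` snaps approximately regular samples to an integer
(row, col) lattice, tolerating displacements up to 10% of the spacing;
unoccupied nodes are reported as holes. The assignment is invariant to
translating all coordinates.

## Moran's I and the permutation test

Global Moran's I is computed in its unstandardized form

    I = n Σᵢⱼ wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / [ (Σᵢⱼ wᵢⱼ) Σᵢ (xᵢ − x̄)² ]

with binary rook weights: wᵢⱼ = 1 iff the two samples occupy laterally
adjacent lattice nodes. No row standardization is applied — the
equation above already divides by Σwᵢⱼ. Failed samples and lattice
holes contribute no edges; neighbors across a hole are simply not
connected, which keeps the statistic well-defined on incomplete
designs. Constant inputs raise (zero denominator) rather than return 0.

Significance comes from a Monte Carlo permutation test (default 1000
permutations): values are shuffled uniformly over the sample positions
and the pseudo p-value (1 + b)/(1 + m) includes the observed statistic,
so p ≥ 1/(m+1) and the test is exact-level by construction. The default
tail is one-sided (`greater`), since clustering of similar values is
the alternative of interest; `less` and `two_sided` (doubled smaller
tail, capped at 1) are available. Fewer than 19 permutations cannot
resolve α = 0.05 and raise.

Calibration: on 500 independent white-noise surveys of the island
design the rejection rate at α = 0.05 sits inside 5% ± 2.5% (the
acceptance suite re-measures this), and power against a field with
variogram range 3× the lattice spacing exceeds 90%.

## Interpolators

**IDW.** z(c) = Σ vᵢ dᵢ⁻ᵖ / Σ dᵢ⁻ᵖ over *all* data points (global
neighborhood), default power p = 2. A cell center within 10⁻¹² cell
sizes of a data point snaps to that point's value, making IDW an exact
interpolator. Predictions are bounded by the data range.

**Variogram estimation and fitting.** The Matheron estimator
γ(h_k) = Σ_pairs (zᵢ − zⱼ)² / (2 N_k) is binned into equal-width lags on
(0, max_dist], default max_dist = half the maximum pairwise distance
and 10 lags. Ten lags (not more) keep each bin populated by a few
hundred pairs at the ~90-sample designs this toolkit targets;
sparse bins make single-realization fits erratic. Candidate models —
spherical, exponential, gaussian (effective-range convention: 95% of
the sill at the stated range) — are fitted for (nugget, partial sill,
range) by least squares weighted by pair counts under nonnegativity
bounds, with the range capped at the largest lag distance (beyond the
sampled lag span the range is not identifiable). The model with the
highest weighted determination coefficient r² wins. If every fit fails,
a pure-nugget model at the pooled variance is returned and flagged
(`fallback=True`).

**Ordinary kriging.** Per prediction cell the system
[Γ 1; 1ᵀ 0][λ; μ] = [γ₀; 1] is solved with Γᵢⱼ = γ(dᵢⱼ) and zero
diagonal; weights sum to 1 by the unbiasedness constraint, and
coincident data points are averaged beforehand. Two conventions matter:

- *Neighborhood.* The default is a moving neighborhood of the 12
  nearest data points per cell (on a square lattice: the first three
  neighbor shells), the way GIS kriging tools operate; `max_points=None`
  solves one global system (a single LU factorization shared by all
  cells, tractable well beyond 85 points). The moving neighborhood is
  what lets IDW outperform kriging on spatially unstructured data — a
  global kriging with a well-fitted near-nugget model degenerates to
  the sample mean, the best possible predictor of noise, which no
  field tool actually attains.
- *Nugget filtering.* The data-data matrix uses γ(0) = 0, but the
  prediction right-hand side uses the h → 0⁺ limit γ(0⁺) = nugget,
  i.e. the nugget is treated as measurement error and the prediction
  estimates the noise-free signal. Consequently kriging with a nonzero
  nugget returns *altered* values at the sampling points — the
  characteristic difference from IDW and the B-spline, and the reason
  kriging wins holdout comparisons on noisy autocorrelated data.

An optional kriging variance raster (λᵀγ₀ + μ, clipped at 0) is
available.

**Multilevel B-spline approximation (MBA).** A hierarchy of cubic
uniform B-spline control lattices over the (slightly padded) raster
extent, starting at 4 × 4 cells and doubling each level; each level
estimates its control points by the local least-squares BA rule
(φ = Σ w²φ_c / Σ w², control points with empty support set to 0) from
the residuals of the sum of all previous levels. Refinement stops when
the maximum residual at the data points reaches `tol` (default 10⁻⁴ of
the data range) or `max_level` (default 11). The converged surface
honors the data to `tol`; between and beyond data points it can
overshoot the data range — useful for depicting patches, costly for
holdout RMSE.

All three interpolators are deterministic and translation-equivariant.

## Validation, stratification, differencing

`holdout_validate` repeats: draw ⌊0.8 n⌋ training samples without
replacement, interpolate on a fixed grid (the full data's bounding
box, so held-out points are always covered), read predictions at the
held-out samples by nearest-cell sampling, score
RMSE = √(Σ(x̂ᵢ − xᵢ)²/n). Default 100 repetitions with per-repetition
values reported (n_reps=1 reproduces a single-draw protocol); a failed
repetition (e.g. singular kriging system) is logged and excluded from
the mean.

`kmeans_stratify` clusters the finite cell values (a single grey
channel) with an *exact* 1-D k-means: optimal clusters of scalar data
are contiguous in sorted order, so the global minimum of the
within-class sum of squares is found by dynamic programming with a
monotone-argmin divide-and-conquer (O(k n log n)). Lloyd-style
iterations with random restarts were measured to land in local optima
on ~10% of small rasters, which is avoidable noise in a published
map. Labels ascend with the centroids (0 = lowest abundance) and
nodata cells stay nodata.

`difference_raster` subtracts co-registered rasters cellwise (nodata
propagates) and summarizes the finite cells by mean, *population* SD,
and the raw (not mean-centered) sum of squares Σd² — a
total-discrepancy measure that satisfies Σd² = n(mean² + SD²).

## Reduced sampling effort

`select_subgrid` retains regular subsets of the grid-indexed samples:
1/2 by parity of row+col (2 phases, spacing ×√2 ≈ 141 m on a 100-m
grid), 1/4 by (row mod 2, col mod 2) (4 phases, 200 m), 1/9 by
(row mod 3, col mod 3) (9 phases, 300 m). Failed samples are never
retained. `rse_simulate` re-interpolates each subgrid on the *same*
grid as the full-data map and reports the difference raster and its
statistics per plan; the sum of squares grows with sparsity, and its
spread across phases grows too — the positioning of a coarse grid
matters more the coarser it is.

## Synthetic surveys

The generator emulates a ~1 km island surveyed on a 9 × 10 lattice at
100-m spacing with 5 randomly failed samples (85 usable), over a truth
raster of 45 × 50 cells at 20 m. Ground truth is a Gaussian random
field realized by dense Cholesky factorization of the covariance
C(h) = sill − γ(h) over the cell centers — exact and fast at this size
(the factor is cached per grid/model). The default field is spherical
with range 300 m (3× the lattice spacing) and total sill 1 with nugget
0.35: read-count-derived abundances carry substantial unstructured
sampling noise, and with roughly a third of the variance in the nugget
the holdout ranking of the interpolators reproduces the regime reported
for real fungal guilds — kriging narrowly ahead of IDW (a few percent),
the B-spline clearly behind both. The white-noise variant (iid cells)
models groups with no spatial structure at the sampled scale.

`synthetic_community` converts per-group propensity fields into OTU
counts: group probabilities are the softmax of the field values at each
sample, reads are multinomial (default 10 000 per sample) and split
evenly among each group's OTUs. This is a composition model — groups
compete for reads, so negative inter-group correlations are expected —
and it makes rarefaction, aggregation and correlation testable end to
end.

What the synthetic data do *not* emulate: taxonomic assignment error,
chimeras and upstream read processing; unequal OTU abundance within
groups; zero inflation beyond multinomial sampling; anisotropy or
trends in the fields; real shoreline geometry (the island is a
rectangle). Passing tests therefore demonstrate that the *estimators
and maps* behave correctly under known spatial structure, not that any
particular real landscape matches the generator.

## Problem sizes in the test and reproduction suites

The heavier checks are Monte Carlo twins of the case-study analyses at
sizes chosen to make their expected orderings statistically stable:
permutation-test calibration over 500 white-noise surveys (999
permutations each); the method comparison over 200 fields per regime
with 4 holdout repetitions each (at these sizes the measured RMSE
margins are 3–7 standard errors); variogram recovery by fitting the
empirical variogram averaged over 50 surveys — a single 85-point
realization of a field whose range is a third of the extent has
heavy-tailed range-estimation error (median ~20%), so the averaged
estimator is the meaningful consistency check.

## Known limitations

- No geodesy: degree coordinates mix units with metre-based thinking;
  supply projected coordinates for metric fidelity.
- Global IDW and global-option kriging are O(cells × points); fine for
  hundreds of points, not thousands.
- The variogram fitter is a WLS curve fit, not REML; anisotropy,
  trends and co-kriging are out of scope.
- MBA control lattices double uniformly; no adaptive refinement.
- The exact 1-D k-means applies because stratification clusters cell
  *values*; multichannel segmentation would need a different tool.
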