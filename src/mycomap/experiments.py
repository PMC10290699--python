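"""Scaled-down study-twin experiments.

Reusable Monte Carlo routines that re-enact the case study's analyses on
synthetic islands: permutation-test calibration, interpolator
exactness, holdout method comparison, variogram recovery, and
reduced-sampling-effort spacing.  They power the reproduction script
and the heavier end of the test suite; each routine is deterministic
given its seed and returns plain numbers.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .autocorr import WeightMatrix, attribute_moran, morans_i, morans_i_naive
from .core_io import GridSpec, sample_raster_at_points
from .interpolation import (
    EmpiricalVariogram,
    InterpolationConfig,
    VariogramModel,
    empirical_variogram,
    fit_variogram_model,
    idw,
    multilevel_bspline,
    ordinary_kriging,
)
from .rse import select_subgrid
from .synthetic import ISLAND_SPACING, island_points
from .validation import holdout_validate

__all__ = [
    "rse_subgrid_spacings",
    "moran_oracle_max_diff",
    "moran_type_i_error",
    "moran_power",
    "exactness_at_samples",
    "method_ordering",
    "variogram_range_recovery",
]

# grid whose cell centers coincide with the island sampling lattice
LATTICE_ALIGNED_GRID = GridSpec(
    x_min=0.0, y_max=900.0, cell_size=ISLAND_SPACING, n_cols=10, n_rows=9
)


def _nearest_neighbor_distances(pts) -> np.ndarray:
    d = squareform(pdist(np.column_stack([pts.x, pts.y])))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def rse_subgrid_spacings(seed: int = 0) -> dict[str, float]:
    """Median nearest-neighbor spacing of the RSE subgrids, in metres.

    Uses one island realization (100-m lattice): retained points of the
    half / quarter / ninth subgrids sit sqrt(2), 2 and 3 lattice steps
    apart.
    """
    pts, _ = island_points(seed=seed)
    out = {}
    for key, frac, off in [
        ("1/2", "1/2", (0,)),
        ("1/4", "1/4", (0, 0)),
        ("1/9", "1/9", (0, 0)),
    ]:
        sub = select_subgrid(pts, frac, off)
        out[key] = float(np.median(_nearest_neighbor_distances(sub)))
    return out


def moran_oracle_max_diff(n_instances: int = 200, seed: int = 0) -> float:
    """Max |vectorized - double-loop| Moran's I over random holed grids."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_instances:
        rows, cols = rng.integers(3, 7, size=2)
        n = rows * cols
        n_holes = int(rng.integers(0, min(4, n - 3)))
        keep = rng.permutation(n)[: n - n_holes]
        rc = np.array([(i // cols, i % cols) for i in sorted(keep)])
        d = np.abs(rc[:, None, :] - rc[None, :, :]).sum(axis=2)
        w = (d == 1).astype(float)
        if not w.any():
            continue
        wm = WeightMatrix(w)
        vals = rng.normal(size=len(rc))
        worst = max(worst, abs(morans_i(vals, wm) - morans_i_naive(vals, wm)))
        done += 1
    return worst


def moran_type_i_error(
    n_fields: int = 500, n_perm: int = 999, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the permutation test on white-noise islands."""
    rej = 0
    for i in range(n_fields):
        pts, _ = island_points(seed=seed + i, white_noise=True)
        res = attribute_moran(pts, "abundance", n_perm=n_perm,
                              seed=seed + n_fields + i)
        rej += res.p < alpha
    return rej / n_fields


def moran_power(
    n_fields: int = 100, n_perm: int = 199, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate on autocorrelated islands (range 3x spacing)."""
    rej = 0
    for i in range(n_fields):
        pts, _ = island_points(seed=seed + i)
        res = attribute_moran(pts, "abundance", n_perm=n_perm,
                              seed=seed + n_fields + i)
        rej += res.p < alpha
    return rej / n_fields


def exactness_at_samples(seed: int = 0) -> dict[str, float]:
    """Max |surface - measured value| at the sample locations per method.

    Interpolates one island realization onto a grid whose cell centers
    coincide with the sampling lattice, so the raster read at a sample
    is the surface value there.  IDW is exact, the converged B-spline is
    exact to its tolerance, and ordinary kriging with a nonzero nugget
    smooths the data instead of honoring them.
    """
    pts, _ = island_points(seed=seed)
    sub = pts.subset(pts.usable("abundance"))
    v = sub.attributes["abundance"]
    spec = LATTICE_ALIGNED_GRID
    out = {}
    r = idw(sub.x, sub.y, v, spec)
    out["idw"] = float(np.abs(sample_raster_at_points(r, sub) - v).max())
    tol = 1e-6 * (v.max() - v.min())
    r = multilevel_bspline(sub.x, sub.y, v, spec, tol=tol)
    out["bspline"] = float(np.abs(sample_raster_at_points(r, sub) - v).max())
    out["bspline_tol"] = tol
    model = fit_variogram_model(empirical_variogram(sub.x, sub.y, v))
    r = ordinary_kriging(sub.x, sub.y, v, model, spec, max_points=12)
    out["kriging"] = float(np.abs(sample_raster_at_points(r, sub) - v).max())
    out["kriging_nugget"] = model.nugget
    return out


def method_ordering(
    n_fields: int = 200,
    n_reps: int = 4,
    white_noise: bool = False,
    cell_size: float = 50.0,
    seed: int = 0,
) -> dict[str, float]:
    """Mean holdout RMSE of IDW, kriging and B-spline over many islands.

    Each replicate draws a fresh island field (autocorrelated or white
    noise), and every method is validated on the same 80% train / 20%
    test splits.
    """
    acc: dict[str, list[float]] = {"idw": [], "kriging": [], "bspline": []}
    for i in range(n_fields):
        pts, _ = island_points(seed=seed + i, white_noise=white_noise)
        for method in acc:
            cfg = InterpolationConfig(method=method, cell_size=cell_size)
            rep = holdout_validate(pts, "abundance", cfg, n_reps=n_reps,
                                   seed=seed + i)
            acc[method].append(rep.mean_rmse)
    return {m: float(np.mean(v)) for m, v in acc.items()}


def variogram_range_recovery(
    n_seeds: int = 50, true_range: float = 300.0, seed: int = 0
) -> dict[str, float]:
    """Fit the seed-averaged empirical variogram of known island fields.

    The Matheron estimator from each 85-point realization is averaged
    over ``n_seeds`` seeds before fitting, giving a Monte Carlo check
    that the estimator + WLS fit recover the generating range.
    """
    model = VariogramModel("spherical", 0.35, 0.65, true_range)
    gammas, lags, counts = [], None, None
    for i in range(n_seeds):
        pts, _ = island_points(model=model, seed=seed + i)
        sub = pts.subset(pts.usable("abundance"))
        ev = empirical_variogram(sub.x, sub.y, sub.attributes["abundance"])
        gammas.append(ev.gamma)
        lags, counts = ev.lag_centers, ev.pair_counts
    fit = fit_variogram_model(
        EmpiricalVariogram(lags, np.mean(gammas, axis=0), counts)
    )
    return {
        "fitted_range": fit.range,
        "true_range": true_range,
        "rel_error": abs(fit.range - true_range) / true_range,
        "kind": fit.kind,
    }
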