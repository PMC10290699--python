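"""Holdout validation, k-means raster stratification, raster differencing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import GridSpec, PointSampleSet, Raster, sample_raster_at_points
from .interpolation import InterpolationConfig, interpolate

__all__ = [
    "ValidationReport",
    "StratifiedRaster",
    "DiffStats",
    "rmse",
    "holdout_validate",
    "kmeans_stratify",
    "difference_raster",
]


@dataclass
class ValidationReport:
    """Per-repetition holdout RMSE for one interpolation method."""

    method: str
    n_reps: int
    train_fraction: float
    rmse_values: list[float]
    failed_reps: int
    seed: int

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse_values))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_reps": self.n_reps,
            "train_fraction": self.train_fraction,
            "rmse": self.rmse_values,
            "mean_rmse": self.mean_rmse,
            "failed_reps": self.failed_reps,
            "seed": self.seed,
        }


@dataclass
class StratifiedRaster:
    """Label raster from 1-D k-means; label 0 is the lowest-abundance class."""

    labels: Raster  # values in {0..k-1}, NaN where input was nodata
    k: int
    centroids: np.ndarray  # ascending
    seed: int


@dataclass
class DiffStats:
    """Cellwise difference summary: mean, population SD, sum of squares."""

    mean: float
    sd: float
    sum_of_squares: float
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "sum_of_squares": self.sum_of_squares,
            "n_cells": self.n_cells,
        }


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean square error sqrt(sum((x_hat - x)^2) / n)."""
    obs = np.asarray(observed, float).ravel()
    pred = np.asarray(predicted, float).ravel()
    if len(obs) != len(pred):
        raise ValueError(f"length mismatch: {len(obs)} observed vs {len(pred)} predicted")
    if len(obs) == 0:
        raise ValueError("empty inputs")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def holdout_validate(
    pts: PointSampleSet,
    attribute: str,
    cfg: InterpolationConfig,
    train_fraction: float = 0.8,
    n_reps: int = 100,
    seed: int = 0,
    spec: GridSpec | None = None,
) -> ValidationReport:
    """Repeated random-holdout RMSE of one interpolator.

    Per repetition, ``floor(train_fraction * n)`` usable samples train
    the interpolator; predictions at the held-out samples are read from
    the raster by nearest-cell sampling and compared to the measured
    values.  The raster geometry is fixed across repetitions (default:
    bounding box of all usable points) so every held-out point is
    covered.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    usable = pts.subset(pts.usable(attribute))
    n = len(usable)
    if n < 5:
        raise ValueError("need at least 5 usable samples")
    if spec is None:
        spec = GridSpec.from_points(usable.x, usable.y, cfg.cell_size, cfg.pad_cells)
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    rmses: list[float] = []
    failed = 0
    for _ in range(n_reps):
        train_idx = rng.choice(n, size=n_train, replace=False)
        test_mask = np.ones(n, dtype=bool)
        test_mask[train_idx] = False
        train = usable.subset(~test_mask)
        test = usable.subset(test_mask)
        try:
            result = interpolate(train, attribute, cfg, spec=spec)
            raster = result[0] if isinstance(result, tuple) else result
            pred = sample_raster_at_points(raster, test)
            rmses.append(rmse(test.attributes[attribute], pred))
        except (ValueError, np.linalg.LinAlgError) as exc:
            failed += 1
            warnings.warn(f"holdout repetition failed: {exc}")
    return ValidationReport(
        method=cfg.method,
        n_reps=n_reps,
        train_fraction=train_fraction,
        rmse_values=rmses,
        failed_reps=failed,
        seed=seed,
    )


def _kmeans_1d_exact(vals: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal 1-D k-means by dynamic programming.

    Optimal clusters of scalar data are contiguous in sorted order, so
    the within-class sum of squares is minimized exactly over the
    (k-1)-cut partitions of the sorted values.  The inner minimization
    has a monotone argmin, solved by divide and conquer in
    O(k n log n).  Returns (labels, centroids ascending).
    """
    order = np.argsort(vals, kind="stable")
    v = vals[order]
    n = len(v)
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def wss(i, j):  # cost of segment [i, j), vectorized in i
        cnt = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / cnt

    cost = np.empty((k, n + 1))
    cut = np.zeros((k, n + 1), dtype=int)
    cost[0, 1:] = wss(np.zeros(n, dtype=int), np.arange(1, n + 1))
    cost[0, 0] = 0.0
    for t in range(1, k):
        def solve(jlo, jhi, ilo, ihi):
            if jlo > jhi:
                return
            jm = (jlo + jhi) // 2
            lo, hi = ilo, min(ihi, jm - 1)
            cand = np.arange(lo, hi + 1)
            c = cost[t - 1, cand] + wss(cand, jm)
            b = int(cand[np.argmin(c)])
            cost[t, jm] = c.min()
            cut[t, jm] = b
            solve(jlo, jm - 1, ilo, b)
            solve(jm + 1, jhi, b, ihi)

        cost[t, : t + 1] = np.inf
        solve(t + 1, n, t, n - 1)
    # backtrack segment boundaries
    bounds = [n]
    j = n
    for t in range(k - 1, 0, -1):
        j = cut[t, j]
        bounds.append(j)
    bounds.append(0)
    bounds = bounds[::-1]
    sorted_labels = np.empty(n, dtype=int)
    centroids = np.empty(k)
    for t in range(k):
        a, b = bounds[t], bounds[t + 1]
        sorted_labels[a:b] = t
        centroids[t] = v[a:b].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = sorted_labels
    return labels, centroids


def kmeans_stratify(
    r: Raster, k: int = 2, seed: int = 0, n_init: int = 10
) -> StratifiedRaster:
    """Segment a raster into k abundance classes by 1-D k-means.

    The finite cell values form a single grey channel and are clustered
    by the globally optimal 1-D k-means (dynamic programming over the
    sorted values), so the partition is the exact minimizer of the
    within-class sum of squares.  Labels ascend with the centroids
    (0 = low, k-1 = high abundance); nodata cells stay nodata.

    ``seed`` and ``n_init`` are accepted for API stability (and the
    seed is recorded in the result) but the exact solver needs neither
    restarts nor randomness.
    """
    finite = np.isfinite(r.values)
    vals = r.values[finite]
    if len(np.unique(vals)) < k:
        raise ValueError(f"fewer than k={k} distinct finite values")
    raw, centroids = _kmeans_1d_exact(vals, k)
    labels = np.full(r.values.shape, np.nan)
    labels[finite] = raw
    return StratifiedRaster(
        labels=Raster(r.spec, labels, r.nodata),
        k=k,
        centroids=centroids,
        seed=seed,
    )


def difference_raster(a: Raster, b: Raster) -> tuple[Raster, DiffStats]:
    """Cellwise a - b with summary statistics over the finite cells.

    nodata in either input propagates.  SD is the population standard
    deviation; the sum of squares is of the raw differences.
    """
    if a.spec != b.spec:
        raise ValueError("raster grids are not co-registered (GridSpec mismatch)")
    d = a.values - b.values
    finite = d[np.isfinite(d)]
    if len(finite) == 0:
        raise ValueError("no overlapping finite cells")
    stats = DiffStats(
        mean=float(finite.mean()),
        sd=float(finite.std()),
        sum_of_squares=float(np.sum(finite**2)),
        n_cells=int(len(finite)),
    )
    return Raster(a.spec, d, a.nodata), stats
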