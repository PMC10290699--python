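"""Scattered-point-to-raster interpolators: IDW, ordinary kriging, MBA.

Three interpolators produce continuous abundance surfaces from the
sampled points:

* inverse distance weighting (IDW) with a global neighborhood and a
  configurable power (default 2);
* ordinary kriging with a variogram fitted to the data (Matheron
  empirical estimator, weighted least-squares model fit, the permissible
  model with the highest determination coefficient wins);
* multilevel B-spline approximation (MBA): a hierarchy of cubic uniform
  B-spline control lattices, each level fitting the residuals of the
  previous one and doubling the lattice resolution.

IDW and a converged B-spline honor the data at the sample points;
ordinary kriging with a nonzero nugget generally does not — it is the
only one of the three that returns altered values at the sampling
points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist, pdist, squareform

from .core_io import GridSpec, PointSampleSet, Raster

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "InterpolationConfig",
    "idw",
    "empirical_variogram",
    "fit_variogram_model",
    "ordinary_kriging",
    "multilevel_bspline",
    "interpolate",
]

_SNAP_FACTOR = 1e-12  # IDW: a cell center closer than this x cell_size is "at" a point


# ---------------------------------------------------------------------------
# Variograms

def _gamma_spherical(h, nugget, psill, rng):
    h = np.asarray(h, float)
    g = np.where(
        h >= rng,
        nugget + psill,
        nugget + psill * (1.5 * h / rng - 0.5 * (h / rng) ** 3),
    )
    return np.where(h > 0, g, 0.0)


def _gamma_exponential(h, nugget, psill, rng):
    h = np.asarray(h, float)
    g = nugget + psill * (1.0 - np.exp(-3.0 * h / rng))
    return np.where(h > 0, g, 0.0)


def _gamma_gaussian(h, nugget, psill, rng):
    h = np.asarray(h, float)
    g = nugget + psill * (1.0 - np.exp(-3.0 * (h / rng) ** 2))
    return np.where(h > 0, g, 0.0)


def _gamma_nugget(h, nugget, psill, rng):
    h = np.asarray(h, float)
    return np.where(h > 0, nugget + psill, 0.0)


_GAMMA_FUNCS = {
    "spherical": _gamma_spherical,
    "exponential": _gamma_exponential,
    "gaussian": _gamma_gaussian,
    "nugget": _gamma_nugget,
}


@dataclass
class EmpiricalVariogram:
    """Matheron semivariance estimates per distance bin."""

    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        self.lag_centers = np.asarray(self.lag_centers, float)
        self.gamma = np.asarray(self.gamma, float)
        self.pair_counts = np.asarray(self.pair_counts, int)
        if not np.all(np.diff(self.lag_centers) > 0):
            raise ValueError("lag centers must be strictly increasing")


@dataclass
class VariogramModel:
    """Permissible variogram: gamma(0) = 0, nondecreasing in distance.

    The effective range convention is used for exponential and gaussian
    kinds (gamma reaches 95% of the sill at ``range``).
    """

    kind: str
    nugget: float
    partial_sill: float
    range: float
    r2: float = float("nan")
    fallback: bool = False  # True when fitting failed and a nugget model was substituted

    def __post_init__(self) -> None:
        if self.kind not in _GAMMA_FUNCS:
            raise ValueError(f"unknown variogram kind {self.kind!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range <= 0:
            raise ValueError("need nugget >= 0, partial_sill >= 0, range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h) -> np.ndarray:
        return _GAMMA_FUNCS[self.kind](h, self.nugget, self.partial_sill, self.range)

    def covariance(self, h) -> np.ndarray:
        """C(h) = sill - gamma(h), the second-order-stationary covariance."""
        return self.sill - self(h)

    def gamma_filtered(self, h) -> np.ndarray:
        """gamma with the nugget as measurement error: the h -> 0+ limit.

        Used for the prediction right-hand side of the kriging system,
        so the estimate at a data location is the nugget-filtered
        (noise-free) signal rather than the noisy datum — kriging with a
        nonzero nugget therefore returns altered values at the sampling
        points, unlike IDW and the converged B-spline.
        """
        h = np.asarray(h, float)
        at_zero = self.nugget + (self.partial_sill if self.kind == "nugget" else 0.0)
        return np.where(h > 0, self(h), at_zero)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range": self.range,
            "r2": self.r2,
            "fallback": self.fallback,
        }


@dataclass
class InterpolationConfig:
    """Which interpolator to run and with what parameters."""

    method: str = "idw"
    cell_size: float = 1.0
    idw_power: float = 2.0
    bspline_max_level: int = 11
    bspline_tol: float | None = None  # default 1e-4 * value range
    kriging_model: VariogramModel | None = None  # None -> auto-fit
    kriging_max_points: int | None = 12  # moving neighborhood; None = global
    variogram_kinds: tuple[str, ...] = ("spherical", "exponential", "gaussian")
    pad_cells: int = 1

    def __post_init__(self) -> None:
        if self.method not in ("idw", "bspline", "kriging"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


# ---------------------------------------------------------------------------
# IDW

def idw(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    spec: GridSpec,
    power: float = 2.0,
) -> Raster:
    """Inverse-distance-weighted surface over all data points.

    z(c) = sum v_i d_i^-p / sum d_i^-p with a global neighborhood; a
    cell center coinciding with a data point takes that point's value
    exactly (IDW is an exact interpolator).
    """
    x, y, values = _clean_xyv(x, y, values)
    if power <= 0:
        raise ValueError("power must be positive")
    gx, gy = spec.center_mesh()
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    d = cdist(cells, np.column_stack([x, y]))
    snap = d < _SNAP_FACTOR * spec.cell_size
    with np.errstate(divide="ignore"):
        wts = d ** (-power)
    out = np.empty(len(cells))
    hit = snap.any(axis=1)
    if hit.any():
        out[hit] = values[np.argmax(snap[hit], axis=1)]
    rest = ~hit
    out[rest] = (wts[rest] @ values) / wts[rest].sum(axis=1)
    return Raster(spec, out.reshape(spec.n_rows, spec.n_cols))


# ---------------------------------------------------------------------------
# Empirical variogram + model fitting

def empirical_variogram(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    n_lags: int = 10,
    max_dist: float | None = None,
) -> EmpiricalVariogram:
    """Matheron estimator on equal-width distance bins.

    gamma(h_k) = (1 / 2N_k) * sum over pairs in bin k of (z_i - z_j)^2,
    with bins on (0, max_dist] (default max_dist = half the maximum
    pairwise distance).  Empty bins are dropped.  Ten lags keep each bin
    populated by a few hundred pairs at the ~90-sample design this
    toolkit targets; sparser designs may need fewer.
    """
    x, y, values = _clean_xyv(x, y, values)
    if len(x) < 2:
        raise ValueError("need at least two points")
    d = pdist(np.column_stack([x, y]))
    if d.max() == 0:
        raise ValueError("all points coincident")
    if max_dist is None:
        max_dist = d.max() / 2.0
    sq = pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    which = np.digitize(d, edges[1:], right=True)
    keep = d <= max_dist
    lag_centers, gamma, counts = [], [], []
    for k in range(n_lags):
        m = keep & (which == k) & (d > 0)
        nk = int(m.sum())
        if nk == 0:
            continue
        lag_centers.append((edges[k] + edges[k + 1]) / 2.0)
        gamma.append(sq[m].sum() / (2.0 * nk))
        counts.append(nk)
    return EmpiricalVariogram(np.array(lag_centers), np.array(gamma), np.array(counts))


def fit_variogram_model(
    ev: EmpiricalVariogram,
    kinds: tuple[str, ...] = ("spherical", "exponential", "gaussian"),
) -> VariogramModel:
    """Weighted least-squares fit; the kind with the best r-squared wins.

    Each candidate kind is fitted for (nugget, partial_sill, range) by
    least squares weighted by pair counts under nonnegativity bounds;
    the determination coefficient is computed on the same weighted fit.
    If no kind can be fitted, a pure-nugget model at the sample variance
    is returned with ``fallback=True``.
    """
    if len(ev.lag_centers) < 3:
        raise ValueError("need at least 3 variogram lags to fit a model")
    h, g, n = ev.lag_centers, ev.gamma, ev.pair_counts.astype(float)
    sigma = 1.0 / np.sqrt(n)  # curve_fit: weights N_k on squared residuals
    gmax = max(g.max(), 1e-12)
    hmax = h.max()
    best: VariogramModel | None = None
    for kind in kinds:
        fn = _GAMMA_FUNCS[kind]
        p0 = (max(g[0] / 2.0, 1e-10), max(gmax - g[0] / 2.0, 1e-10), hmax / 2.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    fn, h, g, p0=p0, sigma=sigma, absolute_sigma=True,
                    # range is unidentifiable beyond the sampled lag span
                    bounds=([0.0, 0.0, 1e-10 * hmax], [np.inf, np.inf, hmax]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        resid = g - fn(h, *popt)
        ss_res = float(np.sum(n * resid**2))
        gbar = float(np.sum(n * g) / n.sum())
        ss_tot = float(np.sum(n * (g - gbar) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        model = VariogramModel(kind, float(popt[0]), float(popt[1]), float(popt[2]), r2=r2)
        if best is None or model.r2 > best.r2:
            best = model
    if best is None:
        var = float(np.sum(n * g) / n.sum())
        return VariogramModel("nugget", var, 0.0, hmax, r2=0.0, fallback=True)
    return best


# ---------------------------------------------------------------------------
# Ordinary kriging

def ordinary_kriging(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    spec: GridSpec,
    return_variance: bool = False,
    max_points: int | None = None,
):
    """Ordinary kriging, optionally with a moving neighborhood.

    Per cell center the system

        [Gamma 1; 1^T 0] [lambda; mu] = [gamma0; 1]

    is solved, with Gamma_ij = gamma(d_ij) and gamma(0) = 0; the
    prediction is lambda^T v and the weights sum to 1 by construction.
    Coincident data points are averaged before solving.

    ``max_points`` limits the neighborhood to the nearest data points
    per cell (moving-window kriging, as GIS kriging tools do); ``None``
    uses every point (one global system).
    """
    x, y, values = _clean_xyv(x, y, values)
    x, y, values = _average_duplicates(x, y, values)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two non-coincident points")
    if max_points is not None and max_points < n:
        return _moving_window_kriging(
            x, y, values, model, spec, max_points, return_variance
        )
    pts = np.column_stack([x, y])
    gamma_mat = model(squareform(pdist(pts)))
    np.fill_diagonal(gamma_mat, 0.0)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma_mat
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    try:
        lu = lu_factor(a)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises ValueError
        raise ValueError("singular kriging system") from exc
    if not np.all(np.isfinite(lu[0])):
        raise ValueError("singular kriging system (near-duplicate points?)")
    gx, gy = spec.center_mesh()
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    rhs = np.empty((n + 1, len(cells)))
    rhs[:n] = model.gamma_filtered(cdist(pts, cells))
    rhs[n] = 1.0
    sol = lu_solve(lu, rhs)
    if not np.all(np.isfinite(sol)):
        raise ValueError("singular kriging system (near-duplicate points?)")
    lam = sol[:n]
    pred = values @ lam
    raster = Raster(spec, pred.reshape(spec.n_rows, spec.n_cols))
    if not return_variance:
        return raster
    var = np.einsum("ij,ij->j", sol[:n], rhs[:n]) + sol[n]
    var_raster = Raster(spec, np.maximum(var, 0.0).reshape(spec.n_rows, spec.n_cols))
    return raster, var_raster


def _moving_window_kriging(
    x, y, values, model, spec, max_points: int, return_variance: bool
):
    """Per-cell OK systems over the ``max_points`` nearest data points."""
    k = max_points
    if k < 2:
        raise ValueError("max_points must be at least 2")
    pts = np.column_stack([x, y])
    gx, gy = spec.center_mesh()
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    d = cdist(cells, pts)
    nn = np.argpartition(d, k - 1, axis=1)[:, :k]  # (ncells, k)
    npts = pts[nn]  # (ncells, k, 2)
    diff = npts[:, :, None, :] - npts[:, None, :, :]
    gam = model(np.sqrt((diff**2).sum(axis=-1)))
    idx = np.arange(k)
    gam[:, idx, idx] = 0.0
    nc = len(cells)
    a = np.zeros((nc, k + 1, k + 1))
    a[:, :k, :k] = gam
    a[:, :k, k] = 1.0
    a[:, k, :k] = 1.0
    rhs = np.empty((nc, k + 1))
    rhs[:, :k] = model.gamma_filtered(np.take_along_axis(d, nn, axis=1))
    rhs[:, k] = 1.0
    sol = np.linalg.solve(a, rhs[..., None])[..., 0]
    if not np.all(np.isfinite(sol)):
        raise ValueError("singular kriging system (near-duplicate points?)")
    lam = sol[:, :k]
    pred = np.einsum("ck,ck->c", lam, values[nn])
    raster = Raster(spec, pred.reshape(spec.n_rows, spec.n_cols))
    if not return_variance:
        return raster
    var = np.einsum("ck,ck->c", sol[:, :k], rhs[:, :k]) + sol[:, k]
    return raster, Raster(spec, np.maximum(var, 0.0).reshape(spec.n_rows, spec.n_cols))


def kriging_weights(
    x: np.ndarray,
    y: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray,
) -> np.ndarray:
    """Ordinary-kriging weights (n_points x n_targets) at target locations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    pts = np.column_stack([x, y])
    gamma_mat = model(squareform(pdist(pts)))
    np.fill_diagonal(gamma_mat, 0.0)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = gamma_mat
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    rhs = np.empty((n + 1, len(targets)))
    rhs[:n] = model.gamma_filtered(cdist(pts, np.asarray(targets, float)))
    rhs[n] = 1.0
    return np.linalg.solve(a, rhs)[:n]


# ---------------------------------------------------------------------------
# Multilevel B-spline approximation (MBA)

def _bspline_basis(t: np.ndarray) -> np.ndarray:
    """The four cubic uniform B-spline basis values at parameter t in [0,1).

    Returns shape (len(t), 4) for control points k-1..k+2.
    """
    t = np.asarray(t, float)
    t2 = t * t
    t3 = t2 * t
    b0 = (1 - t) ** 3 / 6.0
    b1 = (3 * t3 - 6 * t2 + 4) / 6.0
    b2 = (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0
    b3 = t3 / 6.0
    return np.stack([b0, b1, b2, b3], axis=-1)


class _BsplineLevel:
    """One control lattice of the MBA hierarchy (BA algorithm)."""

    def __init__(self, x0, y0, width, height, m, n):
        # m x n interior cells; control lattice (m+3) x (n+3) with one
        # ring outside the domain (indices -1..m+1 mapped to 0..m+2)
        self.x0, self.y0 = x0, y0
        self.hx = width / m
        self.hy = height / n
        self.m, self.n = m, n
        self.phi = np.zeros((m + 3, n + 3))

    def _locate(self, x, y):
        s = (np.asarray(x, float) - self.x0) / self.hx
        t = (np.asarray(y, float) - self.y0) / self.hy
        i = np.clip(np.floor(s).astype(int), 0, self.m - 1)
        j = np.clip(np.floor(t).astype(int), 0, self.n - 1)
        return i, j, s - i, t - j

    def fit(self, x, y, z):
        """BA control-point estimation from scattered residuals."""
        i, j, u, v = self._locate(x, y)
        bu = _bspline_basis(u)  # (npts, 4)
        bv = _bspline_basis(v)
        w = bu[:, :, None] * bv[:, None, :]  # (npts, 4, 4)
        w2 = w * w
        sum_w2 = w2.sum(axis=(1, 2))  # per point
        phi_c = w * (z / sum_w2)[:, None, None]  # point-wise phi contribution
        num = np.zeros_like(self.phi)
        den = np.zeros_like(self.phi)
        rows = i[:, None, None] + np.arange(4)[None, :, None]
        cols = j[:, None, None] + np.arange(4)[None, None, :]
        rows, cols = np.broadcast_arrays(rows, cols)
        np.add.at(num, (rows.ravel(), cols.ravel()), (w2 * phi_c).ravel())
        np.add.at(den, (rows.ravel(), cols.ravel()), w2.ravel())
        with np.errstate(invalid="ignore", divide="ignore"):
            self.phi = np.where(den > 0, num / den, 0.0)

    def __call__(self, x, y):
        i, j, u, v = self._locate(x, y)
        bu = _bspline_basis(u)
        bv = _bspline_basis(v)
        out = np.zeros(len(bu))
        for a in range(4):
            for b in range(4):
                out += bu[:, a] * bv[:, b] * self.phi[i + a, j + b]
        return out


def multilevel_bspline(
    x: np.ndarray,
    y: np.ndarray,
    values: np.ndarray,
    spec: GridSpec,
    max_level: int = 11,
    tol: float | None = None,
) -> Raster:
    """Multilevel B-spline approximation of scattered data.

    Starting from a 4x4-cell cubic B-spline control lattice over the
    (slightly padded) raster extent, each level fits the residuals left
    by the previous levels with the BA local least-squares rule and the
    lattice resolution doubles.  Refinement stops when the maximum
    residual at the data points drops to ``tol`` (default 1e-4 of the
    value range) or ``max_level`` lattices have been used.  The summed
    surface is evaluated at the raster cell centers.
    """
    x, y, values = _clean_xyv(x, y, values)
    vrange = float(values.max() - values.min())
    if tol is None:
        tol = 1e-4 * vrange if vrange > 0 else 1e-12
    # pad so no data point sits exactly on the lattice boundary
    eps = 1e-9 * max(spec.x_max - spec.x_min, spec.y_max - spec.y_min, 1.0)
    x0 = min(spec.x_min, x.min()) - eps
    y0 = min(spec.y_min, y.min()) - eps
    x1 = max(spec.x_max, x.max()) + eps
    y1 = max(spec.y_max, y.max()) + eps
    gx, gy = spec.center_mesh()
    cx, cy = gx.ravel(), gy.ravel()
    resid = values.astype(float).copy()
    surface = np.zeros(len(cx))
    m = n = 4
    for _ in range(max_level):
        lvl = _BsplineLevel(x0, y0, x1 - x0, y1 - y0, m, n)
        lvl.fit(x, y, resid)
        resid = resid - lvl(x, y)
        surface = surface + lvl(cx, cy)
        if np.abs(resid).max() <= tol:
            break
        m *= 2
        n *= 2
    return Raster(spec, surface.reshape(spec.n_rows, spec.n_cols))


# ---------------------------------------------------------------------------
# Dispatcher

def interpolate(
    pts: PointSampleSet,
    attribute: str,
    cfg: InterpolationConfig,
    spec: GridSpec | None = None,
):
    """Interpolate one attribute with the configured method.

    Samples failed for the attribute are excluded.  ``spec`` defaults to
    the usable points' bounding box padded by one cell.  For kriging
    with ``kriging_model=None`` the variogram is fitted automatically;
    the fitted model is returned alongside the raster in that case.
    """
    mask = pts.usable(attribute)
    x, y = pts.x[mask], pts.y[mask]
    v = pts.attributes[attribute][mask]
    if spec is None:
        spec = GridSpec.from_points(x, y, cfg.cell_size, cfg.pad_cells)
    if cfg.method == "idw":
        return idw(x, y, v, spec, power=cfg.idw_power)
    if cfg.method == "bspline":
        return multilevel_bspline(
            x, y, v, spec, max_level=cfg.bspline_max_level, tol=cfg.bspline_tol
        )
    model = cfg.kriging_model
    if model is None:
        ev = empirical_variogram(x, y, v)
        model = fit_variogram_model(ev, cfg.variogram_kinds)
        raster = ordinary_kriging(
            x, y, v, model, spec, max_points=cfg.kriging_max_points
        )
        return raster, model
    return ordinary_kriging(x, y, v, model, spec, max_points=cfg.kriging_max_points)


# ---------------------------------------------------------------------------

def _clean_xyv(x, y, values):
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    v = np.asarray(values, float).ravel()
    if not (len(x) == len(y) == len(v)):
        raise ValueError("x, y, values must have equal lengths")
    if len(x) == 0:
        raise ValueError("need at least one data point")
    ok = np.isfinite(v)
    return x[ok], y[ok], v[ok]


def _average_duplicates(x, y, values):
    coords = np.column_stack([x, y])
    uniq, inv = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return x, y, values
    sums = np.zeros(len(uniq))
    cnts = np.zeros(len(uniq))
    np.add.at(sums, inv, values)
    np.add.at(cnts, inv, 1.0)
    return uniq[:, 0], uniq[:, 1], sums / cnts
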