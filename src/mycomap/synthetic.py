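"""Synthetic landscapes: Gaussian random fields, grid samples, OTU tables.

Every stage of the mapping workflow is testable without sequencing data:
a ground-truth abundance surface is simulated as a Gaussian random field
with a chosen variogram (or as white noise), sampled on a regular
lattice emulating the island case-study design (9 x 10 points at 100-m
spacing, 5 failed samples), and optionally turned into multinomial OTU
read counts through a softmax composition link.

The GRF is realized by dense Cholesky factorization of the covariance
C(h) = sill - gamma(h) over the cell centers — exact, and comfortably
fast at desk scale (a few thousand cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import AbundanceTable, GroupMapping
from .core_io import (
    GridSpec,
    PointSampleSet,
    Raster,
    infer_grid_index,
    sample_raster_at_points,
)
from .interpolation import VariogramModel

__all__ = [
    "FieldSpec",
    "SyntheticCommunitySpec",
    "gaussian_random_field",
    "white_noise_field",
    "sample_field_on_grid",
    "synthetic_community",
    "island_points",
    "ISLAND_GRID",
]

# Case-study-like design: 9 rows x 10 columns at 100-m spacing, with the
# truth raster at 20-m cells (45 x 50 = 2250 cells).
ISLAND_GRID = GridSpec(x_min=0.0, y_max=900.0, cell_size=20.0, n_cols=50, n_rows=45)
ISLAND_SPACING = 100.0
ISLAND_N_FAILED = 5


@dataclass
class FieldSpec:
    """Recipe for one ground-truth surface."""

    kind: str = "grf"  # grf | white_noise
    variogram: VariogramModel | None = None  # grf only
    mean: float = 0.0
    variance: float = 1.0  # white_noise only
    grid: GridSpec = field(default_factory=lambda: ISLAND_GRID)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("grf", "white_noise"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.kind == "grf" and self.variogram is None:
            raise ValueError("grf fields need a variogram model")


@dataclass
class SyntheticCommunitySpec:
    """Recipe for a multi-group community over shared extent."""

    group_fields: dict[str, FieldSpec]
    reads_per_sample: int = 10000
    otus_per_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        grids = {id(f.grid): f.grid for f in self.group_fields.values()}
        specs = list(grids.values())
        if any(s != specs[0] for s in specs[1:]):
            raise ValueError("group fields must share the same grid extent")


_chol_cache: dict[tuple, np.ndarray] = {}


def _covariance_cholesky(spec: GridSpec, model: VariogramModel) -> np.ndarray:
    """Cholesky factor of the cell-center covariance (cached per recipe)."""
    key = (
        spec, model.kind, round(model.nugget, 12), round(model.partial_sill, 12),
        round(model.range, 12),
    )
    if key in _chol_cache:
        return _chol_cache[key]
    from scipy.spatial.distance import pdist, squareform

    gx, gy = spec.center_mesh()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    cov = model.covariance(squareform(pdist(pts)))
    np.fill_diagonal(cov, model.sill)
    jitter = 1e-10 * max(model.sill, 1.0)
    try:
        chol = np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance not positive semidefinite even after jitter"
        ) from exc
    _chol_cache[key] = chol
    return chol


def gaussian_random_field(spec: FieldSpec) -> Raster:
    """Realize one field as a raster; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    n = grid.n_rows * grid.n_cols
    if spec.kind == "white_noise":
        vals = spec.mean + np.sqrt(spec.variance) * rng.standard_normal(n)
    else:
        chol = _covariance_cholesky(grid, spec.variogram)
        vals = spec.mean + chol @ rng.standard_normal(n)
    return Raster(grid, vals.reshape(grid.n_rows, grid.n_cols))


def white_noise_field(grid: GridSpec, mean: float = 0.0, variance: float = 1.0,
                      seed: int = 0) -> Raster:
    return gaussian_random_field(
        FieldSpec(kind="white_noise", mean=mean, variance=variance, grid=grid,
                  seed=seed)
    )


def sample_field_on_grid(
    fields: Raster | dict[str, Raster],
    spacing: float,
    n_failed: int = 0,
    seed: int = 0,
    attribute: str = "value",
) -> PointSampleSet:
    """Sample field(s) on a regular square lattice inside the extent.

    The lattice starts half a spacing in from the top-left corner;
    attribute values are nearest-cell reads of the raster.  ``n_failed``
    randomly chosen samples are flagged failed (all attributes NaN),
    emulating samples that yielded no sequencing data.
    """
    if isinstance(fields, Raster):
        fields = {attribute: fields}
    grid = next(iter(fields.values())).spec
    for r in fields.values():
        if r.spec != grid:
            raise ValueError("all fields must share one grid")
    if spacing < grid.cell_size:
        raise ValueError("lattice spacing smaller than raster cell size")
    xs = np.arange(grid.x_min + spacing / 2.0, grid.x_max, spacing)
    ys = np.arange(grid.y_max - spacing / 2.0, grid.y_min, -spacing)
    gx, gy = np.meshgrid(xs, ys)
    n = gx.size
    ids = np.array([f"s{i + 1:03d}" for i in range(n)], dtype=object)
    pts = PointSampleSet(sample_id=ids, x=gx.ravel(), y=gy.ravel())
    attrs = {name: sample_raster_at_points(r, pts) for name, r in fields.items()}
    if n_failed > 0:
        rng = np.random.default_rng(seed)
        failed_idx = rng.choice(n, size=n_failed, replace=False)
        for v in attrs.values():
            v[failed_idx] = np.nan
    pts.attributes = {k: np.asarray(v, float) for k, v in attrs.items()}
    return infer_grid_index(pts, spacing)


def island_points(
    model: VariogramModel | None = None,
    seed: int = 0,
    attribute: str = "abundance",
    white_noise: bool = False,
) -> tuple[PointSampleSet, Raster]:
    """The case-study-like fixture: 90 lattice samples, 5 failed.

    Returns the point set and the underlying truth raster.  Default
    variogram: spherical, range 300 m (3x the lattice spacing), total
    sill 1 with a nugget of 0.35 — read-count abundances carry strong
    small-scale sampling noise, so a sizeable share of the variance is
    spatially unstructured.
    """
    if white_noise:
        truth = white_noise_field(ISLAND_GRID, seed=seed)
    else:
        if model is None:
            model = VariogramModel("spherical", nugget=0.35, partial_sill=0.65,
                                   range=300.0)
        truth = gaussian_random_field(
            FieldSpec(kind="grf", variogram=model, grid=ISLAND_GRID, seed=seed)
        )
    pts = sample_field_on_grid(
        truth, ISLAND_SPACING, n_failed=ISLAND_N_FAILED, seed=seed,
        attribute=attribute,
    )
    return pts, truth


def synthetic_community(
    spec: SyntheticCommunitySpec, pts: PointSampleSet
) -> tuple[AbundanceTable, GroupMapping]:
    """Multinomial OTU read counts from per-group propensity fields.

    Group propensities at each sample are the softmax of the group field
    values at the sample location; reads are drawn multinomially and
    split uniformly among each group's OTUs.  Deterministic given the
    community seed.
    """
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.group_fields)
    fields = {g: gaussian_random_field(fs) for g, fs in spec.group_fields.items()}
    logit = np.column_stack(
        [sample_raster_at_points(fields[g], pts) for g in groups]
    )
    logit -= logit.max(axis=1, keepdims=True)
    prop = np.exp(logit)
    prop /= prop.sum(axis=1, keepdims=True)
    otu_ids = [
        f"otu_{g}_{i + 1}" for g in groups for i in range(spec.otus_per_group)
    ]
    counts = np.zeros((len(pts), len(otu_ids)), dtype=np.int64)
    for si in range(len(pts)):
        group_reads = rng.multinomial(spec.reads_per_sample, prop[si])
        col = 0
        for gi, g in enumerate(groups):
            split = rng.multinomial(
                group_reads[gi], np.full(spec.otus_per_group, 1.0 / spec.otus_per_group)
            )
            counts[si, col:col + spec.otus_per_group] = split
            col += spec.otus_per_group
    table = AbundanceTable(
        pd.DataFrame(counts, index=list(pts.sample_id), columns=otu_ids)
    )
    mapping = GroupMapping(
        {"trophic_guild": {
            f"otu_{g}_{i + 1}": g
            for g in groups for i in range(spec.otus_per_group)
        }}
    )
    return table, mapping
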