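"""Georeferenced point samples and rasters.

Coordinates are planar throughout: distances are Euclidean in whatever
units the input table uses (metres for projected data, degrees otherwise).
No geodesy is performed. Rasters are north-up, row-major, cell-center
registered: row 0 is the northernmost row and values live at cell centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "PointSampleSet",
    "GridSpec",
    "Raster",
    "read_points",
    "write_raster",
    "read_raster",
    "sample_raster_at_points",
    "infer_grid_index",
]

# GeoTIFF / GDAL tag codes used for georeferencing single-band grids.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class PointSampleSet:
    """Georeferenced samples with named abundance attributes.

    ``attributes[name]`` is a float array aligned with ``sample_id``;
    NaN marks a failed measurement (sample collected, no data).  Failed
    values are excluded from every downstream statistic and interpolation.
    ``grid_index`` is an optional ``(n, 2)`` integer array of (row, col)
    placements on the sampling lattice (-1 where not assigned).
    """

    sample_id: np.ndarray  # object/str array, unique
    x: np.ndarray
    y: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)
    grid_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.sample_id)
        if len(self.x) != n or len(self.y) != n:
            raise ValueError("coordinate arrays must match sample_id length")
        ids, counts = np.unique(self.sample_id, return_counts=True)
        if (counts > 1).any():
            dupes = ids[counts > 1].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("missing or non-finite coordinates")
        coords = np.column_stack([self.x, self.y])
        if len(np.unique(coords, axis=0)) != n:
            raise ValueError("two samples share identical (x, y) coordinates")
        self.attributes = {
            k: np.asarray(v, dtype=float) for k, v in self.attributes.items()
        }
        for k, v in self.attributes.items():
            if len(v) != n:
                raise ValueError(f"attribute {k!r} length mismatch")

    def __len__(self) -> int:
        return len(self.sample_id)

    @property
    def failed(self) -> np.ndarray:
        """Samples with no data for any attribute (all-NaN rows)."""
        if not self.attributes:
            return np.zeros(len(self), dtype=bool)
        stack = np.column_stack(list(self.attributes.values()))
        return np.isnan(stack).all(axis=1)

    def usable(self, attribute: str) -> np.ndarray:
        """Boolean mask of samples carrying a value for ``attribute``."""
        return np.isfinite(self.attributes[attribute])

    def subset(self, mask: np.ndarray) -> "PointSampleSet":
        return PointSampleSet(
            sample_id=self.sample_id[mask],
            x=self.x[mask],
            y=self.y[mask],
            attributes={k: v[mask] for k, v in self.attributes.items()},
            grid_index=None if self.grid_index is None else self.grid_index[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"sample_id": self.sample_id, "x": self.x, "y": self.y}
        d.update(self.attributes)
        return pd.DataFrame(d)


@dataclass(frozen=True)
class GridSpec:
    """Square-cell raster geometry; (x_min, y_max) is the top-left corner."""

    x_min: float
    y_max: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as 1-D arrays (xs per column, ys per row)."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = self.cell_centers()
        return np.meshgrid(xs, ys)

    @classmethod
    def from_points(
        cls, x: np.ndarray, y: np.ndarray, cell_size: float, pad_cells: int = 1
    ) -> "GridSpec":
        """Bounding box of the points padded by ``pad_cells`` cells."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        pad = pad_cells * cell_size
        x_min = x.min() - pad
        y_max = y.max() + pad
        n_cols = max(1, math.ceil((x.max() + pad - x_min) / cell_size))
        n_rows = max(1, math.ceil((y_max - (y.min() - pad)) / cell_size))
        return cls(x_min, y_max, cell_size, n_cols, n_rows)


@dataclass
class Raster:
    """Regular grid of values; NaN cells are nodata in memory.

    ``nodata`` is the sentinel written to (and recognized in) files.
    """

    spec: GridSpec
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match spec "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )

    @property
    def finite_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(self.spec, values, self.nodata)


def read_points(
    path,
    x_col: str = "x",
    y_col: str = "y",
    id_col: str = "sample_id",
) -> PointSampleSet:
    """Read a point-sample table from CSV.

    Every column other than id/x/y becomes an attribute; non-numeric or
    empty cells mark that sample as failed for that attribute (NaN).
    """
    df = pd.read_csv(path)
    for col in (id_col, x_col, y_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if df[[x_col, y_col]].isna().any().any():
        raise ValueError("missing coordinate values")
    attr_cols = [c for c in df.columns if c not in (id_col, x_col, y_col)]
    attributes = {
        c: pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        for c in attr_cols
    }
    return PointSampleSet(
        sample_id=df[id_col].astype(str).to_numpy(dtype=object),
        x=df[x_col].to_numpy(dtype=float),
        y=df[y_col].to_numpy(dtype=float),
        attributes=attributes,
    )


def write_points(pts: PointSampleSet, path) -> None:
    pts.to_frame().to_csv(path, index=False)


def write_raster(r: Raster, path, format: str = "esri_ascii") -> None:
    """Write a raster as ESRI ASCII grid or single-band float64 GeoTIFF."""
    if format == "esri_ascii":
        _write_esri_ascii(r, path)
    elif format == "geotiff":
        _write_geotiff(r, path)
    else:
        raise ValueError(f"unknown raster format {format!r}")


def read_raster(path, format: str | None = None) -> Raster:
    """Read a raster; format inferred from the file when not given."""
    if format is None:
        with open(path, "rb") as fh:
            magic = fh.read(4)
        format = "geotiff" if magic[:2] in (b"II", b"MM") else "esri_ascii"
    if format == "esri_ascii":
        return _read_esri_ascii(path)
    if format == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {format!r}")


def _write_esri_ascii(r: Raster, path) -> None:
    spec = r.spec
    vals = np.where(np.isfinite(r.values), r.values, r.nodata)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.x_min!r}\n"
        f"yllcorner {spec.y_min!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {r.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # repr keeps full precision so the round-trip is bit-identical
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_esri_ascii(path) -> Raster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value") and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    values = np.array([v for row in rows for v in row], dtype=float)
    values = values.reshape(n_rows, n_cols)
    values = np.where(values == nodata, np.nan, values)
    spec = GridSpec(
        x_min=header["xllcorner"],
        y_max=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_cols=n_cols,
        n_rows=n_rows,
    )
    return Raster(spec, values, nodata)


def _write_geotiff(r: Raster, path) -> None:
    spec = r.spec
    vals = np.where(np.isfinite(r.values), r.values, r.nodata)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, spec.x_min, spec.y_max, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(r.nodata)),
    ]
    tifffile.imwrite(path, vals.astype(np.float64), extratags=extratags)


def _read_geotiff(path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    n_rows, n_cols = values.shape
    spec = GridSpec(
        x_min=float(tiepoint[3]),
        y_max=float(tiepoint[4]),
        cell_size=float(scale[0]),
        n_cols=n_cols,
        n_rows=n_rows,
    )
    values = np.where(values == nodata, np.nan, values)
    return Raster(spec, values, nodata)


def point_to_cell(spec: GridSpec, x: np.ndarray, y: np.ndarray):
    """(row, col) of the cell whose center is nearest to each point."""
    col = np.floor((np.asarray(x, float) - spec.x_min) / spec.cell_size)
    row = np.floor((spec.y_max - np.asarray(y, float)) / spec.cell_size)
    return row.astype(int), col.astype(int)


def sample_raster_at_points(r: Raster, pts: PointSampleSet) -> np.ndarray:
    """Nearest-cell raster values at the sample locations.

    No interpolation between cells: each point takes the value of the
    cell containing it (the QGIS Point Sampling Tool rule).  Points
    outside the raster extent raise; nodata propagates as NaN.
    """
    spec = r.spec
    row, col = point_to_cell(spec, pts.x, pts.y)
    bad = (row < 0) | (row >= spec.n_rows) | (col < 0) | (col >= spec.n_cols)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"sample {pts.sample_id[i]!r} at ({pts.x[i]}, {pts.y[i]}) "
            "falls outside the raster extent"
        )
    return r.values[row, col]


def infer_grid_index(
    pts: PointSampleSet, spacing: float, tolerance: float = 0.1
) -> PointSampleSet:
    """Assign (row, col) lattice indices to approximately regular samples.

    Row 0 is the northernmost occupied row, column 0 the westernmost
    occupied column.  A point farther than ``tolerance * spacing`` from
    its nearest lattice node, or two points claiming one node, raise.
    Unoccupied interior nodes are lattice holes (see :func:`grid_holes`).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    col_f = (pts.x - pts.x.min()) / spacing
    row_f = (pts.y.max() - pts.y) / spacing
    col = np.rint(col_f).astype(int)
    row = np.rint(row_f).astype(int)
    off = np.hypot(col_f - col, row_f - row) * spacing
    tol = tolerance * spacing
    if (off > tol).any():
        i = int(np.argmax(off))
        raise ValueError(
            f"sample {pts.sample_id[i]!r} lies {off[i]:.1f} units from the "
            f"nearest lattice node (tolerance {tol:.1f})"
        )
    nodes = np.column_stack([row, col])
    uniq, counts = np.unique(nodes, axis=0, return_counts=True)
    if (counts > 1).any():
        clash = uniq[counts > 1][0]
        raise ValueError(
            f"two samples map to the same lattice node (row={clash[0]}, "
            f"col={clash[1]})"
        )
    return replace(pts, grid_index=nodes)


def grid_holes(pts: PointSampleSet) -> list[tuple[int, int]]:
    """Unoccupied (row, col) nodes inside the occupied lattice envelope."""
    if pts.grid_index is None:
        raise ValueError("grid_index not assigned; call infer_grid_index first")
    occupied = {tuple(rc) for rc in pts.grid_index}
    rows = pts.grid_index[:, 0]
    cols = pts.grid_index[:, 1]
    return [
        (r, c)
        for r in range(rows.min(), rows.max() + 1)
        for c in range(cols.min(), cols.max() + 1)
        if (r, c) not in occupied
    ]
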