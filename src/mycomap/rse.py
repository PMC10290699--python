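"""Reduced-sampling-effort (RSE) simulation.

How much map is lost when fewer samples are collected?  Regular
subgrids retain 1/2, 1/4 or 1/9 of the lattice points (nearest-neighbor
spacing x sqrt(2), x2 and x3 respectively on a square grid), the map is
re-interpolated on the full map's grid, and the difference raster
quantifies the discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .core_io import GridSpec, PointSampleSet, Raster
from .interpolation import InterpolationConfig, interpolate
from .validation import DiffStats, difference_raster

__all__ = ["RSEPlan", "RSEReport", "select_subgrid", "rse_simulate", "all_phases"]

_FRACTIONS = {
    Fraction(1, 1): 1,
    Fraction(1, 2): 2,
    Fraction(1, 4): 4,
    Fraction(1, 9): 9,
}


def _parse_fraction(fraction) -> Fraction:
    f = Fraction(fraction)
    if f not in _FRACTIONS:
        raise ValueError(
            f"unsupported fraction {fraction!r}; use 1, 1/2, 1/4 or 1/9"
        )
    return f


@dataclass(frozen=True)
class RSEPlan:
    """One subgrid selection: retained fraction and lattice phase.

    Phases: 1/2 keeps points with (row + col) % 2 == offset (2 phases,
    offset an int); 1/4 keeps (row % 2, col % 2) == offset; 1/9 keeps
    (row % 3, col % 3) == offset.  Fraction 1 (degenerate, keeps all)
    is offered for testing.
    """

    fraction: Fraction
    offset: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        f = _parse_fraction(self.fraction)
        object.__setattr__(self, "fraction", f)
        off = self.offset
        if isinstance(off, int):
            off = (off,)
        off = tuple(int(o) for o in off)
        object.__setattr__(self, "offset", off)
        if f == Fraction(1, 2):
            if len(off) != 1 or off[0] not in (0, 1):
                raise ValueError("fraction 1/2 needs offset in {0, 1}")
        elif f == Fraction(1, 4):
            if len(off) != 2 or any(o not in (0, 1) for o in off):
                raise ValueError("fraction 1/4 needs offset (r%2, c%2)")
        elif f == Fraction(1, 9):
            if len(off) != 2 or any(o not in (0, 1, 2) for o in off):
                raise ValueError("fraction 1/9 needs offset (r%3, c%3)")

    def expected_spacing(self, base_spacing: float) -> float:
        """Nearest-neighbor spacing among retained points."""
        factor = {
            Fraction(1, 1): 1.0,
            Fraction(1, 2): float(np.sqrt(2.0)),
            Fraction(1, 4): 2.0,
            Fraction(1, 9): 3.0,
        }[self.fraction]
        return base_spacing * factor

    def mask(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        f = self.fraction
        if f == Fraction(1, 1):
            return np.ones(len(rows), dtype=bool)
        if f == Fraction(1, 2):
            return (rows + cols) % 2 == self.offset[0]
        if f == Fraction(1, 4):
            return (rows % 2 == self.offset[0]) & (cols % 2 == self.offset[1])
        return (rows % 3 == self.offset[0]) & (cols % 3 == self.offset[1])


def all_phases(fraction) -> list[RSEPlan]:
    """Every lattice phase of a fraction, lexicographically ordered."""
    f = _parse_fraction(fraction)
    if f == Fraction(1, 1):
        return [RSEPlan(f, (0,))]
    if f == Fraction(1, 2):
        return [RSEPlan(f, (p,)) for p in (0, 1)]
    mod = 2 if f == Fraction(1, 4) else 3
    return [RSEPlan(f, (r, c)) for r in range(mod) for c in range(mod)]


@dataclass
class RSEResult:
    """Outcome of one plan: retained samples, map, discrepancy."""

    plan: RSEPlan
    retained_ids: list[str]
    raster: Raster
    diff: Raster
    stats: DiffStats


@dataclass
class RSEReport:
    attribute: str
    method: str
    full_raster: Raster
    results: list[RSEResult] = field(default_factory=list)


def select_subgrid(pts: PointSampleSet, fraction, offset=(0,)) -> PointSampleSet:
    """Retain the samples on a regular subgrid of the sampling lattice.

    Failed samples are never retained.
    """
    if pts.grid_index is None:
        raise ValueError("grid_index not assigned; call infer_grid_index first")
    plan = RSEPlan(_parse_fraction(fraction), offset)
    rows = pts.grid_index[:, 0]
    cols = pts.grid_index[:, 1]
    keep = plan.mask(rows, cols) & ~pts.failed
    if not keep.any():
        raise ValueError(f"plan {plan} retains no samples")
    return pts.subset(keep)


def rse_simulate(
    pts: PointSampleSet,
    attribute: str,
    cfg: InterpolationConfig,
    plans: list[RSEPlan],
    spec: GridSpec | None = None,
) -> RSEReport:
    """Compare reduced-sampling maps to the full-data map.

    The full map is interpolated from all usable samples; each plan's
    subgrid is re-interpolated on the same GridSpec and subtracted from
    the full map (full - reduced), so positive differences mean the
    reduced map underestimates.
    """
    usable = pts.subset(pts.usable(attribute))
    if spec is None:
        spec = GridSpec.from_points(usable.x, usable.y, cfg.cell_size, cfg.pad_cells)
    full = _as_raster(interpolate(pts, attribute, cfg, spec=spec))
    report = RSEReport(attribute=attribute, method=cfg.method, full_raster=full)
    for plan in plans:
        sub = select_subgrid(pts, plan.fraction, plan.offset)
        reduced = _as_raster(interpolate(sub, attribute, cfg, spec=spec))
        diff, stats = difference_raster(full, reduced)
        report.results.append(
            RSEResult(
                plan=plan,
                retained_ids=[str(s) for s in sub.sample_id],
                raster=reduced,
                diff=diff,
                stats=stats,
            )
        )
    return report


def _as_raster(result) -> Raster:
    return result[0] if isinstance(result, tuple) else result
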