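"""Effort-proportional pseudo-absence generation.

Presence-only boat-survey data carry the spatial bias of the survey
itself: cells near the harbour are searched far more often than the outer
bay.  To balance that bias, background ("pseudo-absence") points are
generated in proportion to the survey effort, both in number and in
space:

* the monthly count follows the effort formula
  ``absences = effort_hours * 4 + search_days * 5``;
* the locations are drawn from a kernel-smoothed density surface of the
  month's boat tracklines, so absences concentrate where the boats
  actually looked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridError, RasterGrid
from .records import EffortRecord, PseudoAbsenceSet, Trackline


class GenerationError(RuntimeError):
    """Sampling was requested from a degenerate density surface."""


HOURS_WEIGHT = 4.0
DAYS_WEIGHT = 5.0


def n_pseudo_absences(effort: EffortRecord) -> int:
    """Pseudo-absence count for one month's effort.

    ``count = effort_hours * 4 + search_days * 5``, rounded half-up to the
    nearest integer (the inputs are usually integers, so rounding rarely
    engages).
    """
    if effort.effort_hours < 0 or effort.search_days < 0:
        raise ValueError("effort inputs must be nonnegative")
    raw = effort.effort_hours * HOURS_WEIGHT + effort.search_days * DAYS_WEIGHT
    return int(math.floor(raw + 0.5))


@dataclass
class DensitySurface:
    """Nonnegative per-cell weights summing to 1 over valid cells."""

    grid: RasterGrid

    def __post_init__(self) -> None:
        vals = self.grid.valid_values()
        if np.any(vals < 0):
            raise GridError("density values must be nonnegative")
        total = vals.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise GridError(f"density must sum to 1 over valid cells, got {total}")


def _segment_cell_lengths(
    grid: RasterGrid, p0: np.ndarray, p1: np.ndarray, accum: np.ndarray
) -> None:
    """Apportion the length of one segment among the cells it crosses."""
    x0, y0 = grid.origin
    cs = grid.cell_size
    # Parametrise the segment and split at every grid-line crossing.
    d = p1 - p0
    ts = [0.0, 1.0]
    for axis, (o, sign) in enumerate([(x0, 1.0), (y0, -1.0)]):
        if d[axis] == 0:
            continue
        # Index coordinate along this axis: col = (x - x0)/cs, row = (y0 - y)/cs
        a0 = (p0[axis] - o) * sign / cs
        a1 = (p1[axis] - o) * sign / cs
        lo, hi = sorted((a0, a1))
        for k in range(int(np.ceil(lo)), int(np.floor(hi)) + 1):
            t = (k - a0) / (a1 - a0)
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = np.unique(np.clip(ts, 0.0, 1.0))
    seg_len = float(np.hypot(*d))
    nrows, ncols = grid.shape
    for ta, tb in zip(ts[:-1], ts[1:]):
        if tb <= ta:
            continue
        mid = p0 + d * (0.5 * (ta + tb))
        col = int(np.floor((mid[0] - x0) / cs))
        row = int(np.floor((y0 - mid[1]) / cs))
        if 0 <= row < nrows and 0 <= col < ncols:
            accum[row, col] += seg_len * (tb - ta)


def trackline_density(
    tracklines: list[Trackline],
    grid: RasterGrid,
    bandwidth: float = 2.0,
) -> DensitySurface:
    """Kernel-smoothed trackline length density, normalised to sum 1.

    Per-cell accumulated polyline length is smoothed with a Gaussian
    kernel of ``bandwidth`` cells (0 = no smoothing), zeroed on nodata
    cells, and normalised over the remaining cells.
    """
    if not tracklines:
        raise GridError("need at least one trackline")
    accum = np.zeros(grid.shape)
    for tl in tracklines:
        for p0, p1 in zip(tl.vertices[:-1], tl.vertices[1:]):
            _segment_cell_lengths(grid, np.asarray(p0, float), np.asarray(p1, float), accum)
    if accum.sum() == 0:
        raise GridError("all tracklines fall outside the grid")
    if bandwidth > 0:
        accum = ndimage.gaussian_filter(accum, sigma=bandwidth)
    accum[grid.nodata_mask] = 0.0
    total = accum.sum()
    if total == 0:
        raise GridError("trackline density vanished after masking")
    out = RasterGrid(accum / total, grid.cell_size, tuple(grid.origin), grid.nodata_mask.copy())
    return DensitySurface(out)


def sample_absences(
    density: DensitySurface,
    count: int,
    seed: int,
    month_id: str = "",
    exclude_cells: set[tuple[int, int]] | None = None,
) -> PseudoAbsenceSet:
    """Draw ``count`` points from the density surface.

    Cells are drawn with replacement with probability proportional to
    their density value; each drawn point is then placed uniformly at
    random within its cell.  ``exclude_cells`` (opt-in) zeroes the listed
    cells before drawing — presence cells are kept by default.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    rng = np.random.default_rng(seed)
    grid = density.grid
    weights = grid.values.copy()
    if exclude_cells:
        for r, c in exclude_cells:
            weights[r, c] = 0.0
    flat = weights.ravel()
    total = flat.sum()
    if count == 0:
        return PseudoAbsenceSet(month_id, np.empty((0, 2)), seed)
    if total <= 0:
        raise GenerationError("cannot sample: density surface is all zero")
    idx = rng.choice(flat.size, size=count, replace=True, p=flat / total)
    rows, cols = np.unravel_index(idx, grid.shape)
    u = rng.random((count, 2))
    x0, y0 = grid.origin
    xs = x0 + (cols + u[:, 0]) * grid.cell_size
    ys = y0 - (rows + u[:, 1]) * grid.cell_size
    return PseudoAbsenceSet(month_id, np.column_stack([xs, ys]), seed)


def absences_for_month(
    effort: EffortRecord,
    tracklines: list[Trackline],
    grid: RasterGrid,
    seed: int,
    bandwidth: float = 2.0,
) -> PseudoAbsenceSet:
    """Full monthly pipeline: count from effort, locations from tracklines."""
    count = n_pseudo_absences(effort)
    if count == 0:
        return PseudoAbsenceSet(effort.month_id, np.empty((0, 2)), seed)
    density = trackline_density(tracklines, grid, bandwidth=bandwidth)
    return sample_absences(density, count, seed, month_id=effort.month_id)
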