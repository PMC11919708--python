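"""Planar raster grids.

All spatial data in this package live on a single planar grid in metres.
A :class:`RasterGrid` stores one 2-D layer with its cell size, the (x, y)
of the grid's top-left corner, and a boolean nodata mask.  Row 0 is the
northernmost row (raster convention): x grows with column index, y shrinks
with row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridError(ValueError):
    """Invalid grid construction or out-of-extent access."""


@dataclass
class RasterGrid:
    """One georeferenced layer on a regular planar grid.

    Parameters
    ----------
    values
        2-D float array of layer values (layer units).
    cell_size
        Edge length of a square cell, metres. Must be positive.
    origin
        (x, y) of the grid's top-left (north-west) corner.
    nodata_mask
        Boolean array, True where the cell carries no data. Defaults to
        all-False.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GridError("values must be a 2-D array")
        if min(self.values.shape) < 2:
            raise GridError(f"degenerate grid shape {self.values.shape}: need >= 2 cells per axis")
        if not self.cell_size > 0:
            raise GridError(f"cell_size must be positive, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise GridError("nodata_mask shape differs from values shape")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise GridError("non-finite values outside the nodata mask")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's bounding box."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.cell_size, x0 + ncols * self.cell_size, y0)

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to its (row, col) cell.

        Cells are half-open: a point on a shared edge belongs to the cell to
        the right (in x) / below (in y). Points on the far outer edge are
        clamped into the last cell so that the closed extent is covered.
        """
        if not self.contains(x, y):
            raise GridError(f"point ({x}, {y}) outside grid extent {self.extent}")
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        nrows, ncols = self.shape
        return min(row, nrows - 1), min(col, ncols - 1)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    # -- convenience --------------------------------------------------------

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            self.values.copy(), self.cell_size, tuple(self.origin), self.nodata_mask.copy()
        )

    def same_grid_as(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )
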