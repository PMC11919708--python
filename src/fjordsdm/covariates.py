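"""Covariate stack assembly, harmonisation, and collinearity screening.

Six environmental predictors drive the models: sea-surface temperature
(°C), chlorophyll-a concentration (mg/m³), sea-surface salinity (PSU),
depth (m, negative below sea level), seabed slope (°), and distance to
shore (m).  The first three vary monthly; the last three are static.
All layers are harmonised onto one planar grid before modelling: resampled
to a common cell size, and depth cells at or above sea level masked out so
land never enters the training data.

Collinearity among the six covariates is screened (pairwise Pearson
correlation and variance inflation factors) but never used to drop
variables — the report is informational.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridError, RasterGrid

#: Canonical covariate order used everywhere (tables, bases, importances).
COVARIATES = ("sst", "chlorophyll_a", "salinity", "depth", "slope", "dist_shore")

DYNAMIC_COVARIATES = ("sst", "chlorophyll_a", "salinity")
STATIC_COVARIATES = ("depth", "slope", "dist_shore")


@dataclass
class EnvStack:
    """The six covariate layers for one month on a shared grid."""

    month_id: str
    layers: dict[str, RasterGrid]

    def __post_init__(self) -> None:
        missing = set(COVARIATES) - set(self.layers)
        if missing:
            raise GridError(f"stack {self.month_id} missing layers: {sorted(missing)}")
        ref = self.layers[COVARIATES[0]]
        for name in COVARIATES:
            if not self.layers[name].same_grid_as(ref):
                raise GridError(f"layer {name} not on the shared grid of stack {self.month_id}")

    @property
    def grid(self) -> RasterGrid:
        return self.layers[COVARIATES[0]]

    def combined_nodata(self) -> np.ndarray:
        """Cells where any layer lacks data (excluded from modelling)."""
        mask = np.zeros(self.grid.shape, dtype=bool)
        for name in COVARIATES:
            mask |= self.layers[name].nodata_mask
        return mask

    def as_array(self) -> np.ndarray:
        """(nrows, ncols, 6) array in canonical covariate order."""
        return np.stack([self.layers[name].values for name in COVARIATES], axis=-1)


@dataclass
class ScreeningReport:
    """Pairwise Pearson matrix, VIFs, and flagged high-correlation pairs."""

    pearson: pd.DataFrame
    vif: pd.Series
    flags: list[tuple[str, str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.pearson.copy()
        out["vif"] = self.vif
        return out


def resample_layer(layer: RasterGrid, target_cell_size: float) -> RasterGrid:
    """Resample a layer to a new cell size over the same extent.

    Continuous values are interpolated bilinearly between source cell
    centres; the nodata mask is transferred by nearest neighbour so gaps
    propagate rather than bleed.
    """
    if target_cell_size <= 0:
        raise GridError("target_cell_size must be positive")
    xmin, ymin, xmax, ymax = layer.extent
    if target_cell_size > (xmax - xmin) or target_cell_size > (ymax - ymin):
        raise GridError("target cell size coarser than the layer extent")
    n_rows = max(2, int(round((ymax - ymin) / target_cell_size)))
    n_cols = max(2, int(round((xmax - xmin) / target_cell_size)))

    # Fractional source indices of the target cell centres.
    ratio_r = (ymax - ymin) / layer.cell_size / n_rows
    ratio_c = (xmax - xmin) / layer.cell_size / n_cols
    rows = (np.arange(n_rows) + 0.5) * ratio_r - 0.5
    cols = (np.arange(n_cols) + 0.5) * ratio_c - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")

    filled = layer.values.copy()
    if layer.nodata_mask.any():
        # Fill gaps with nearest valid value so bilinear weights stay sane;
        # the mask re-imposes nodata afterwards.
        idx = ndimage.distance_transform_edt(
            layer.nodata_mask, return_distances=False, return_indices=True
        )
        filled = filled[tuple(idx)]
    values = ndimage.map_coordinates(filled, [rr, cc], order=1, mode="nearest")
    mask = (
        ndimage.map_coordinates(
            layer.nodata_mask.astype(np.uint8), [rr, cc], order=0, mode="nearest"
        )
        .astype(bool)
    )
    values[mask] = np.nan
    out = RasterGrid(
        np.where(mask, 0.0, values), target_cell_size, tuple(layer.origin), mask
    )
    return out


def mask_depth(depth: RasterGrid) -> RasterGrid:
    """Set every cell at or above sea level (value >= 0) to nodata.

    Idempotent; negative (under-water) cells pass through untouched.
    """
    out = depth.copy()
    above = (out.values >= 0) & ~out.nodata_mask
    out.nodata_mask |= above
    out.values = np.where(out.nodata_mask, 0.0, out.values)
    return out


def extract_at_points(
    stack: EnvStack, points: np.ndarray
) -> tuple[pd.DataFrame, int]:
    """Read the six covariate values under each point.

    Returns a DataFrame with one row per retained point (columns in
    canonical covariate order plus x, y) and the count of points excluded
    because they fell on a nodata cell of any layer.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    grid = stack.grid
    nodata = stack.combined_nodata()
    arr = stack.as_array()
    rows = []
    excluded = 0
    for x, y in points:
        r, c = grid.point_to_cell(x, y)  # raises GridError outside extent
        if nodata[r, c]:
            excluded += 1
            continue
        rows.append((x, y, *arr[r, c]))
    table = pd.DataFrame(rows, columns=["x", "y", *COVARIATES])
    return table, excluded


def screen_collinearity(
    training_table: pd.DataFrame, flag_threshold: float = 0.7
) -> ScreeningReport:
    """Pearson matrix, VIFs, and |r| flags over the six covariate columns.

    VIF_j = 1 / (1 - R²_j) from regressing covariate j on the other five.
    A zero-variance column yields undefined (NaN) correlations and VIF
    with a warning, never an exception.  Pairs with |r| >= ``flag_threshold``
    are flagged for the report; nothing is dropped.
    """
    cols = [c for c in COVARIATES if c in training_table.columns]
    if len(training_table) < 3:
        raise ValueError("need at least 3 rows to screen collinearity")
    X = training_table[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing covariate values in training table")

    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        bad = [c for c, d in zip(cols, degenerate) if d]
        warnings.warn(f"zero-variance covariates, screening undefined for: {bad}")

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan

    vif = np.full(len(cols), np.nan)
    for j in range(len(cols)):
        if degenerate[j]:
            continue
        others = [k for k in range(len(cols)) if k != j and not degenerate[k]]
        if not others:
            vif[j] = 1.0
            continue
        A = np.column_stack([np.ones(len(X)), X[:, others]])
        yj = X[:, j]
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"covariate {cols[j]} perfectly explained by the others; VIF undefined")
            continue
        vif[j] = 1.0 / (1.0 - r2)

    flags = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            r = corr[a, b]
            if np.isfinite(r) and abs(r) >= flag_threshold:
                flags.append((cols[a], cols[b], float(r)))

    return ScreeningReport(
        pearson=pd.DataFrame(corr, index=cols, columns=cols),
        vif=pd.Series(vif, index=cols, name="vif"),
        flags=flags,
    )


def mean_over_scenes(layers: list[RasterGrid]) -> RasterGrid:
    """Nodata-aware arithmetic mean of several co-registered layers.

    A cell is nodata in the output only if it is nodata in every input
    (intended for monthly means of repeated satellite scenes).
    """
    if not layers:
        raise GridError("need at least one layer")
    ref = layers[0]
    for lay in layers[1:]:
        if not lay.same_grid_as(ref):
            raise GridError("layers not co-registered")
    stack = np.stack([np.where(l.nodata_mask, np.nan, l.values) for l in layers])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    mask = np.isnan(mean)
    return RasterGrid(np.where(mask, 0.0, mean), ref.cell_size, tuple(ref.origin), mask)
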