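"""Synthetic fjord study system.

Generates everything the analysis pipeline consumes — static bathymetry
with derived slope and shore distance, monthly dynamic covariate fields,
a known ("true") suitability surface, harbour-based boat tours with
month-varying effort, and presence points sampled from the true
suitability with the survey's observation bias built in — so the whole
pipeline is testable end to end against a known ground truth.

The geography mimics a bay with a single port: land is a connected margin
along the eastern grid edge and the harbour sits on its coastline.
Dynamic fields are spatially autocorrelated (Gaussian-smoothed white
noise) with a seasonal mean cycle; ranges are plausible for a subarctic
North Atlantic bay: SST in [-1, 14] °C, chlorophyll-a in [0.05, 20] mg/m³
(generated on the log scale), salinity in [30, 36] PSU.

Months are labelled ``"YYYY-MM"``; days within a month are 1..28.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .covariates import COVARIATES, EnvStack
from .grids import GridError, RasterGrid
from .pseudo_absence import GenerationError, trackline_density
from .records import EffortRecord, SightingSet, Trackline

DYNAMIC_RANGES = {
    "sst": (-1.0, 14.0),
    "chlorophyll_a": (0.05, 20.0),
    "salinity": (30.0, 36.0),
}

DAYS_PER_MONTH = 28
HOURS_PER_TOUR = 3.0
#: Tours on an active day are 1 + Poisson(0.43), giving the observed
#: long-run average of 1.43 tours per search day.
EXTRA_TOURS_RATE = 0.43


def _rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic, stream-separated generator for (seed, tokens)."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for tok in tokens:
        entropy.append(zlib.crc32(str(tok).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _month_number(month_id: str) -> int:
    return int(str(month_id).split("-")[1])


@dataclass
class TrueSuitability:
    """Ground-truth occurrence probability surface.

    ``surface = inverse_logit(intercept + sum_j coefficients[j] * layer_j)``
    cell-wise; used to place synthetic presences and to validate that the
    fitted models recover the right spatial ranking.
    """

    coefficients: dict[str, float]
    intercept: float
    surface: RasterGrid


def slope_from_depth(depth: RasterGrid) -> RasterGrid:
    """Seabed slope in degrees from central finite differences of depth."""
    gy, gx = np.gradient(depth.values, depth.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    return RasterGrid(slope, depth.cell_size, tuple(depth.origin), depth.nodata_mask.copy())


def shore_distance(land_mask: np.ndarray, cell_size: float, origin=(0.0, 0.0)) -> RasterGrid:
    """Euclidean distance (m) from each water cell to the nearest land cell."""
    if not land_mask.any():
        raise GridError("no land cells: shore distance undefined")
    dist = ndimage.distance_transform_edt(~land_mask) * cell_size
    return RasterGrid(dist, cell_size, tuple(origin))


def gen_static_layers(
    shape: tuple[int, int],
    cell_size: float,
    seed: int,
    land_fraction: float = 0.15,
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Bathymetry with a land margin, plus derived slope and shore distance.

    Land occupies a wiggly margin along the eastern edge (elevation > 0);
    water deepens away from the coast with smooth noise (depth <= 0).
    """
    nrows, ncols = shape
    if min(nrows, ncols) < 8:
        raise GridError(f"grid too small for a coastline: {shape}, need >= 8x8")
    rng = _rng(seed, "static")
    origin = (0.0, nrows * cell_size)

    margin = max(2, int(round(ncols * land_fraction)))
    wiggle = ndimage.gaussian_filter1d(rng.standard_normal(nrows), sigma=max(2, nrows // 8))
    wiggle = wiggle / (np.abs(wiggle).max() + 1e-12) * max(1, margin // 2)
    coast_col = np.clip(np.round(ncols - margin + wiggle).astype(int), 4, ncols - 1)
    cols = np.arange(ncols)
    land = cols[None, :] >= coast_col[:, None]

    dist_cells = ndimage.distance_transform_edt(~land)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    noise = noise / (noise.std() + 1e-12)
    depth_vals = -(8.0 * dist_cells**0.9 + 10.0 * np.abs(noise))
    depth_vals[~land] = np.minimum(depth_vals[~land], -1.0)
    depth_vals[land] = 5.0 + 3.0 * np.abs(noise[land])

    depth = RasterGrid(depth_vals, cell_size, origin)
    slope = slope_from_depth(depth)
    dist_shore = shore_distance(land, cell_size, origin)
    return depth, slope, dist_shore


def land_mask_from_depth(depth: RasterGrid) -> np.ndarray:
    return depth.values >= 0


def gen_dynamic_layer(
    shape: tuple[int, int],
    cell_size: float,
    month_id: str,
    layer_name: str,
    seed: int,
    smooth_radius: float = 3.0,
) -> RasterGrid:
    """One monthly dynamic field: smoothed noise plus a seasonal mean.

    The seasonal cycle peaks in late summer for SST, in late spring for
    the chlorophyll bloom, and is weak for salinity.  ``smooth_radius`` is
    the Gaussian sigma in cells (0 = raw white noise plus the offset).
    """
    if layer_name not in DYNAMIC_RANGES:
        raise ValueError(f"unknown dynamic layer {layer_name!r}; expected one of {list(DYNAMIC_RANGES)}")
    rng = _rng(seed, "dyn", layer_name, month_id)
    m = _month_number(month_id)
    z = rng.standard_normal(shape)
    if smooth_radius > 0:
        z = ndimage.gaussian_filter(z, sigma=smooth_radius)
        z = z / (z.std() + 1e-12)
    lo, hi = DYNAMIC_RANGES[layer_name]
    if layer_name == "sst":
        mean = 6.5 + 5.5 * np.cos(2 * np.pi * (m - 8) / 12)
        vals = mean + 1.5 * z
    elif layer_name == "chlorophyll_a":
        log_mean = np.log(0.8) + 1.2 * np.cos(2 * np.pi * (m - 5) / 12)
        vals = np.exp(log_mean + 0.5 * z)
    else:  # salinity
        mean = 33.5 - 0.5 * np.cos(2 * np.pi * (m - 7) / 12)
        vals = mean + 0.4 * z
    vals = np.clip(vals, lo, hi)
    nrows = shape[0]
    return RasterGrid(vals, cell_size, (0.0, nrows * cell_size))


def gen_env_stack(
    shape: tuple[int, int],
    cell_size: float,
    month_id: str,
    seed: int,
    static: tuple[RasterGrid, RasterGrid, RasterGrid] | None = None,
    smooth_radius: float = 3.0,
) -> EnvStack:
    """Assemble the six-layer stack for one month (static layers shared)."""
    if static is None:
        static = gen_static_layers(shape, cell_size, seed)
    depth, slope, dist_shore = static
    layers = {
        name: gen_dynamic_layer(shape, cell_size, month_id, name, seed, smooth_radius)
        for name in DYNAMIC_RANGES
    }
    layers.update({"depth": depth, "slope": slope, "dist_shore": dist_shore})
    return EnvStack(month_id, layers)


def make_true_suitability(
    stack: EnvStack,
    coefficients: dict[str, float],
    intercept: float,
    standardize: bool = False,
) -> TrueSuitability:
    """Deterministic suitability surface from the stack's covariates.

    With ``standardize=True`` each layer is z-scored over its valid cells
    before entering the linear combination, so coefficients are comparable
    across layers with different units.
    """
    unknown = set(coefficients) - set(COVARIATES)
    if unknown:
        raise ValueError(f"coefficients for unknown covariates: {sorted(unknown)}")
    grid = stack.grid
    nodata = stack.combined_nodata()
    eta = np.full(grid.shape, float(intercept))
    for name, coef in coefficients.items():
        vals = stack.layers[name].values
        if standardize:
            valid = vals[~nodata]
            sd = valid.std()
            vals = (vals - valid.mean()) / (sd if sd > 0 else 1.0)
        eta = eta + coef * vals
    surface = expit(eta)
    surface = np.where(nodata, 0.0, surface)
    return TrueSuitability(
        dict(coefficients),
        float(intercept),
        RasterGrid(surface, grid.cell_size, tuple(grid.origin), nodata.copy()),
    )


def _random_tour(
    grid: RasterGrid, harbor: tuple[float, float], rng: np.random.Generator, n_steps: int = 24
) -> np.ndarray:
    """One out-and-back path from the harbour into the bay."""
    xmin, ymin, xmax, ymax = grid.extent
    pad = 0.25 * grid.cell_size
    # Head west, away from the eastern land margin; wide initial spread so
    # the fleet covers the whole bay over a month.
    heading = np.pi + rng.uniform(-1.2, 1.2)
    pos = np.array(harbor, dtype=float)
    path = [pos.copy()]
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.35)
        step = rng.uniform(1.0, 3.0) * grid.cell_size
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        pos[0] = np.clip(pos[0], xmin + pad, xmax - pad)
        pos[1] = np.clip(pos[1], ymin + pad, ymax - pad)
        path.append(pos.copy())
    back = path[-2::-1]
    return np.array(path + back)


def simulate_tours(
    grid: RasterGrid,
    harbor: tuple[float, float],
    n_tours: int,
    month_id: str,
    seed: int,
    hours_per_tour: float = HOURS_PER_TOUR,
) -> tuple[list[Trackline], EffortRecord]:
    """Simulate a month of whale-watching tours from the harbour.

    Tours are packed into calendar days 1..28: each active day carries
    ``1 + Poisson(0.43)`` tours (long-run mean 1.43 tours per active day),
    days are filled in order until the requested total is reached.  Effort
    hours are ``hours_per_tour`` per tour; search days is the count of
    days with at least one tour.
    """
    if n_tours < 0:
        raise ValueError("n_tours must be nonnegative")
    if not grid.contains(*harbor):
        raise GridError(f"harbor {harbor} outside grid extent")
    rng = _rng(seed, "tours", month_id)
    if n_tours == 0:
        return [], EffortRecord(month_id, 0.0, 0)

    day_counts: list[int] = []
    remaining = n_tours
    while remaining > 0 and len(day_counts) < DAYS_PER_MONTH:
        k = min(1 + int(rng.poisson(EXTRA_TOURS_RATE)), remaining)
        day_counts.append(k)
        remaining -= k
    while remaining > 0:  # month saturated: pile extras on random days
        day_counts[int(rng.integers(len(day_counts)))] += 1
        remaining -= 1
    days = rng.choice(DAYS_PER_MONTH, size=len(day_counts), replace=False) + 1
    days.sort()

    tracklines = []
    for day, k in zip(days, day_counts):
        for _ in range(k):
            tracklines.append(Trackline(_random_tour(grid, harbor, rng), month_id, int(day)))
    effort = EffortRecord(month_id, hours_per_tour * n_tours, len(day_counts))
    return tracklines, effort


def default_harbor(depth: RasterGrid) -> tuple[float, float]:
    """A water cell adjacent to the coast, mid-grid: the port."""
    land = land_mask_from_depth(depth)
    nrows = depth.shape[0]
    r = nrows // 2
    water_cols = np.where(~land[r])[0]
    c = water_cols.max()  # closest to the eastern land margin
    return depth.cell_center(r, c)


def sample_presences(
    suitability: TrueSuitability,
    tracklines: list[Trackline],
    n_sightings: int,
    seed: int,
    bandwidth: float = 2.0,
) -> SightingSet:
    """Presence points biased by both habitat and observation effort.

    Cells are drawn with probability proportional to
    ``true_suitability × trackline_density`` (the same kernel density used
    for pseudo-absence placement, so the bias and its correction are
    commensurable); points land uniformly within their cell, on water only.
    """
    if n_sightings < 0:
        raise ValueError("n_sightings must be nonnegative")
    surf = suitability.surface
    month_id = tracklines[0].month_id if tracklines else ""
    if n_sightings == 0:
        return SightingSet(month_id, np.empty((0, 2)))
    density = trackline_density(tracklines, surf, bandwidth=bandwidth)
    weights = surf.values * density.grid.values
    weights[surf.nodata_mask] = 0.0
    total = weights.sum()
    if total <= 0:
        raise GenerationError("no water cells with positive weight under the tracklines")
    rng = _rng(seed, "presences", month_id)
    idx = rng.choice(weights.size, size=n_sightings, replace=True, p=weights.ravel() / total)
    rows, cols = np.unravel_index(idx, surf.shape)
    u = rng.random((n_sightings, 2))
    x0, y0 = surf.origin
    xs = x0 + (cols + u[:, 0]) * surf.cell_size
    ys = y0 - (rows + u[:, 1]) * surf.cell_size
    return SightingSet(month_id, np.column_stack([xs, ys]))
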