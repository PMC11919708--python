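"""Readers and writers for the pipeline's on-disk formats.

Rasters are stored as ESRI ASCII grid (.asc) — a plain-text,
GDAL/ArcGIS-compatible single-band format — points and effort tables as
headed CSV, tracklines as GeoJSON LineString features with a ``month_id``
property, and run manifests as JSON with SHA-256 checksums.  All
coordinates are planar metres on the study grid; any lon/lat ingestion
is the job of the dataset adapter, not the core.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import RasterGrid
from .records import EffortRecord, PseudoAbsenceSet, SightingSet, Trackline

NODATA_VALUE = -9999.0


class FormatError(ValueError):
    """A file did not match its expected format."""


class SchemaError(FormatError):
    """A table is missing a required column."""


# -- rasters -----------------------------------------------------------------

def write_raster(grid: RasterGrid, path) -> None:
    """ESRI ASCII grid; values printed at full double precision."""
    nrows, ncols = grid.shape
    x0, y0 = grid.origin
    vals = np.where(grid.nodata_mask, NODATA_VALUE, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {(y0 - nrows * grid.cell_size)!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"nodata_value {NODATA_VALUE!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_raster(path) -> RasterGrid:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            }:
                header[key] = float(parts[1])
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise FormatError(f"{path}: non-numeric raster row: {line!r}") from exc
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise FormatError(f"{path}: missing header field {req!r}")
    values = np.asarray(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(
            f"{path}: data shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", NODATA_VALUE)
    mask = values == nodata
    values = np.where(mask, 0.0, values)
    y0 = header.get("yllcorner", 0.0) + int(header["nrows"]) * header["cellsize"]
    return RasterGrid(values, header["cellsize"], (header.get("xllcorner", 0.0), y0), mask)


# -- tabular points and effort ----------------------------------------------

def _read_table(path, required: list[str]) -> tuple[pd.DataFrame, int]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    frame = pd.read_csv(path)
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    numeric = [c for c in required if c != "month_id"]
    coerced = frame.copy()
    for col in numeric:
        coerced[col] = pd.to_numeric(frame[col], errors="coerce")
    bad = coerced[numeric].isna().any(axis=1)
    n_rejected = int(bad.sum())
    if n_rejected:
        lines = (frame.index[bad] + 2).tolist()  # +2: header + 1-based
        import logging

        logging.getLogger(__name__).warning(
            "%s: rejected %d malformed rows (lines %s)", path, n_rejected, lines
        )
    return coerced.loc[~bad].reset_index(drop=True), n_rejected


def write_points(points: SightingSet | PseudoAbsenceSet, path) -> None:
    points.to_frame().to_csv(path, index=False)


def read_sightings(path) -> list[SightingSet]:
    frame, _ = _read_table(path, ["month_id", "x", "y"])
    return [
        SightingSet(str(mid), grp[["x", "y"]].to_numpy())
        for mid, grp in frame.groupby("month_id", sort=True)
    ]


def read_absences(path) -> list[PseudoAbsenceSet]:
    frame, _ = _read_table(path, ["month_id", "x", "y"])
    out = []
    for mid, grp in frame.groupby("month_id", sort=True):
        seed = int(grp["seed"].iloc[0]) if "seed" in grp.columns else 0
        out.append(PseudoAbsenceSet(str(mid), grp[["x", "y"]].to_numpy(), seed))
    return out


def write_effort(records: list[EffortRecord], path) -> None:
    pd.DataFrame(
        [
            {"month_id": r.month_id, "effort_hours": r.effort_hours, "search_days": r.search_days}
            for r in records
        ]
    ).to_csv(path, index=False)


def read_effort(path) -> list[EffortRecord]:
    frame, _ = _read_table(path, ["month_id", "effort_hours", "search_days"])
    return [
        EffortRecord(str(r.month_id), float(r.effort_hours), int(r.search_days))
        for r in frame.itertuples()
    ]


# -- tracklines --------------------------------------------------------------

def write_tracklines(tracklines: list[Trackline], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(x), float(y)] for x, y in tl.vertices],
            },
            "properties": {"month_id": tl.month_id, "day": tl.day},
        }
        for tl in tracklines
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_tracklines(path) -> list[Trackline]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for feat in data.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "LineString":
            raise FormatError(f"{path}: expected LineString geometries, got {geom.get('type')}")
        props = feat.get("properties", {})
        out.append(
            Trackline(np.asarray(geom["coordinates"], dtype=float),
                      str(props.get("month_id", "")), int(props.get("day", 1)))
        )
    return out


# -- run manifest ------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)  # stage -> rows/cells

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(Path(path))

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _sha256(Path(path))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seeds": self.seeds,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                    "counts": self.counts,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    def verify(self) -> list[str]:
        """Paths whose checksum no longer matches (or which are missing)."""
        bad = []
        for mapping in (self.inputs, self.outputs):
            for p, digest in mapping.items():
                if not Path(p).exists() or _sha256(Path(p)) != digest:
                    bad.append(p)
        return bad


# -- deposited-dataset adapter ----------------------------------------------

EXPECTED_LAYOUT = """\
rasters/<covariate>_<YYYY-MM>.asc   one ASCII grid per covariate per month
                                    (static covariates may use a single
                                     <covariate>.asc shared by all months)
sightings.csv                       columns: month_id, x, y
effort.csv                          columns: month_id, effort_hours, search_days
tracklines.geojson                  LineString features with month_id property
"""


def dataset_adapter(directory):
    """Optional adapter for a locally downloaded survey-data deposit.

    The archive is never fetched automatically; arrange it in the layout
    documented in ``EXPECTED_LAYOUT`` (pre-projected to planar metres)
    and this maps it onto the pipeline's input contracts.  Returns a dict
    with 'sightings', 'effort', 'tracklines', and 'rasters'.
    """
    directory = Path(directory)
    if not directory.exists():
        raise FormatError(
            f"optional adapter: dataset not present at {directory}. "
            f"Expected layout:\n{EXPECTED_LAYOUT}"
        )
    expected = ["sightings.csv", "effort.csv", "tracklines.geojson", "rasters"]
    found = sorted(p.name for p in directory.iterdir())
    missing = [e for e in expected if not (directory / e).exists()]
    if missing:
        raise FormatError(
            f"dataset layout mismatch at {directory}: missing {missing}; found {found}. "
            f"Expected layout:\n{EXPECTED_LAYOUT}"
        )
    rasters: dict[str, RasterGrid] = {}
    for p in sorted((directory / "rasters").glob("*.asc")):
        rasters[p.stem] = read_raster(p)
    return {
        "sightings": read_sightings(directory / "sightings.csv"),
        "effort": read_effort(directory / "effort.csv"),
        "tracklines": read_tracklines(directory / "tracklines.geojson"),
        "rasters": rasters,
    }
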