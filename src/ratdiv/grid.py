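"""Gridded predictor layers: geometry, I/O, harmonisation and point extraction.

Rasters are plain north-up WGS84 lat/lon grids.  On disk they are ESRI ASCII
grids (``.asc``) — a text interchange format readable by every GIS — and in
memory they are float arrays with NaN marking nodata.  The five anthropogenic
predictors (GDP per capita, population density, relative deprivation, travel
time to cities, travel time to ports) are harmonised onto one 2.5-arcmin
(5 km) grid by nearest-neighbour resampling, and predictor vectors are then
read off at sampled localities with complete-case filtering: a locality that
falls on nodata in any layer, or outside the grid, is dropped — no pixel is
ever imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .localities import LocalityRecord

#: canonical predictor layer names, in fixed order
PREDICTORS = (
    "GDP_per_capita_2015",
    "gpw_v4_population_density_2020",
    "povmap.grdi.v1",
    "travel_time_to_cities_12_MOD",
    "travel_time_to_ports_5_MOD",
)

DEFAULT_NODATA = -9999.0


class GridMismatchError(ValueError):
    """Layers do not share one shape and georeferencing."""


@dataclass(frozen=True)
class GridGeometry:
    """North-up rectilinear geographic grid.

    ``west``/``north`` are the outer edges of the upper-left cell; ``xres``
    and ``yres`` are cell sizes in decimal degrees (both positive, rows run
    north to south).
    """

    west: float
    north: float
    xres: float
    yres: float
    nrows: int
    ncols: int

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.xres

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.yres

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_center(self, row, col):
        """Lon/lat of cell centers (vectorised)."""
        lon = self.west + (np.asarray(col) + 0.5) * self.xres
        lat = self.north - (np.asarray(row) + 0.5) * self.yres
        return lon, lat

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.ncols) + 0.5) * self.xres

    def lat_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.nrows) + 0.5) * self.yres

    def containing_cell(self, lon: float, lat: float) -> Optional[tuple[int, int]]:
        """Row/col of the cell containing a point, or None if off-grid.

        Cell membership uses half-open intervals [left, right) in longitude
        and (top, bottom] in latitude; a point exactly on the antimeridian
        (lon == 180) wraps to -180 first.
        """
        if lon == 180.0:
            lon = -180.0
        u = (lon - self.west) / self.xres
        v = (self.north - lat) / self.yres
        col = math.floor(u)
        row = math.ceil(v) - 1
        if lat == self.north:  # top edge belongs to the first row
            row = 0
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def nearest_cell_indices(self, lon: np.ndarray, lat: np.ndarray):
        """Indices of the source cell whose *center* is nearest each point.

        Ties (point equidistant between two centers) resolve to the smaller
        row, then smaller column index.
        """
        u = (np.asarray(lon, dtype=float) - self.west) / self.xres
        v = (self.north - np.asarray(lat, dtype=float)) / self.yres
        # nearest integer to (u - 0.5), ties toward the lower index:
        col = np.ceil(u - 1.0).astype(int)
        row = np.ceil(v - 1.0).astype(int)
        return row, col


@dataclass
class Raster:
    """A single-band grid; NaN marks nodata in memory."""

    values: np.ndarray
    geometry: GridGeometry
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise GridMismatchError(
                f"array shape {self.values.shape} != grid {self.geometry.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


def read_ascii_grid(path: str | Path, nodata_override: Optional[float] = None) -> Raster:
    """Read an ESRI ASCII grid (.asc).  Requires square cells.

    ``nodata_override`` replaces the file's NODATA_value (config key
    ``rasters.nodata``).
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ASCII grid header lacks {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cs = header["cellsize"]
    if "xllcorner" in header:
        west = header["xllcorner"]
        south = header["yllcorner"]
    else:  # corner registration from center registration
        west = header["xllcenter"] - cs / 2
        south = header["yllcenter"] - cs / 2
    data = data.reshape(nrows, ncols)
    nodata = nodata_override if nodata_override is not None else header.get(
        "nodata_value", DEFAULT_NODATA
    )
    values = np.where(np.isclose(data, nodata, rtol=0, atol=1e-9), np.nan, data)
    geom = GridGeometry(
        west=west, north=south + nrows * cs, xres=cs, yres=cs,
        nrows=nrows, ncols=ncols,
    )
    return Raster(values=values, geometry=geom, nodata=nodata)


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.8g") -> None:
    geom = raster.geometry
    if not math.isclose(geom.xres, geom.yres):
        raise ValueError("ASCII grid requires square cells")
    out = np.where(np.isfinite(raster.values), raster.values, raster.nodata)
    header = (
        f"ncols {geom.ncols}\n"
        f"nrows {geom.nrows}\n"
        f"xllcorner {geom.west!r}\n"
        f"yllcorner {geom.south!r}\n"
        f"cellsize {geom.xres!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with Path(path).open("w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


@dataclass
class PredictorStack:
    """The five co-registered predictor layers on one shared grid."""

    layers: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self):
        names = tuple(self.layers)
        if sorted(names) != sorted(PREDICTORS):
            missing = set(PREDICTORS) - set(names)
            extra = set(names) - set(PREDICTORS)
            raise ValueError(
                f"stack must contain exactly the five canonical layers; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        geoms = {r.geometry for r in self.layers.values()}
        if len(geoms) != 1:
            raise GridMismatchError("layers do not share one grid geometry")
        # keep canonical order regardless of input order
        self.layers = {name: self.layers[name] for name in PREDICTORS}

    @property
    def geometry(self) -> GridGeometry:
        return next(iter(self.layers.values())).geometry

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    def complete(self) -> np.ndarray:
        """Boolean grid: cells with valid values in all five layers."""
        ok = np.ones(self.geometry.shape, dtype=bool)
        for r in self.layers.values():
            ok &= r.valid
        return ok

    def as_array(self) -> np.ndarray:
        """(5, nrows, ncols) array in canonical layer order."""
        return np.stack([self.layers[n].values for n in PREDICTORS])


@dataclass
class AnalysisTable:
    """Complete-case matrix of Ho plus the five predictors per locality.

    ``data`` holds one row per retained locality with columns
    ``ho`` + the five canonical predictor names; ``meta`` carries provenance
    (study id, site, coordinates, insularity) aligned by row.
    """

    data: pd.DataFrame
    species: str
    meta: pd.DataFrame

    def __post_init__(self):
        expected = ["ho", *PREDICTORS]
        if list(self.data.columns) != expected:
            raise ValueError(f"analysis table columns must be {expected}")
        if self.data.isna().any().any():
            raise ValueError("analysis table contains missing values")
        if len(self.meta) != len(self.data):
            raise ValueError("meta and data row counts differ")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def predictors(self) -> pd.DataFrame:
        return self.data[list(PREDICTORS)]

    @property
    def ho(self) -> np.ndarray:
        return self.data["ho"].to_numpy()


def resample_nearest(raster: Raster, target_resolution_arcmin: float) -> Raster:
    """Resample a layer to a target resolution by nearest-neighbour lookup.

    Each output cell takes the value of the source cell whose center is
    nearest the output cell center (ties toward the smaller row, then the
    smaller column).  Nodata propagates unchanged — it is never interpolated.
    The output grid covers the source extent, anchored at the source
    north-west corner.
    """
    if target_resolution_arcmin <= 0:
        raise ValueError("target_resolution must be positive")
    res = target_resolution_arcmin / 60.0
    src = raster.geometry
    ncols = max(1, round((src.east - src.west) / res))
    nrows = max(1, round((src.north - src.south) / res))
    out_geom = GridGeometry(
        west=src.west, north=src.north, xres=res, yres=res,
        nrows=nrows, ncols=ncols,
    )
    lon = out_geom.lon_centers()
    lat = out_geom.lat_centers()
    lon2, lat2 = np.meshgrid(lon, lat)
    row, col = src.nearest_cell_indices(lon2, lat2)
    row = np.clip(row, 0, src.nrows - 1)
    col = np.clip(col, 0, src.ncols - 1)
    values = raster.values[row, col]
    return Raster(values=values, geometry=out_geom, nodata=raster.nodata)


def resample_stack(stack: PredictorStack, target_resolution_arcmin: float) -> PredictorStack:
    return PredictorStack(
        layers={
            name: resample_nearest(r, target_resolution_arcmin)
            for name, r in stack.layers.items()
        }
    )


def extract_at_points(
    stack: PredictorStack, records: Sequence[LocalityRecord]
) -> tuple[AnalysisTable, int]:
    """Read the five predictor values at each locality; drop incomplete cases.

    A locality contributes one row holding the value of its containing cell
    in every layer.  Points outside the grid, or on nodata in any single
    layer, are dropped and counted (never imputed).

    Raises
    ------
    ValueError
        If no locality survives complete-case filtering, or records mix
        species.
    """
    if not records:
        raise ValueError("no records supplied")
    species = {r.species for r in records}
    if len(species) > 1:
        raise ValueError(f"records mix species: {sorted(species)}")
    geom = stack.geometry
    arrays = stack.as_array()
    rows_out = []
    meta_out = []
    dropped = 0
    for rec in records:
        cell = geom.containing_cell(rec.lon, rec.lat)
        if cell is None:
            dropped += 1
            continue
        vec = arrays[:, cell[0], cell[1]]
        if not np.all(np.isfinite(vec)):
            dropped += 1
            continue
        rows_out.append([rec.ho, *vec])
        meta_out.append(
            {
                "study_id": rec.study_id,
                "site": rec.site,
                "lon": rec.lon,
                "lat": rec.lat,
                "insularity": rec.insularity,
                "marker": rec.marker,
            }
        )
    if not rows_out:
        raise ValueError("no complete-case localities")
    data = pd.DataFrame(rows_out, columns=["ho", *PREDICTORS])
    meta = pd.DataFrame(meta_out)
    return AnalysisTable(data=data, species=species.pop(), meta=meta), dropped


def read_stack(
    raster_dir: str | Path,
    nodata_override: Optional[Mapping[str, float]] = None,
    suffix: str = ".asc",
) -> PredictorStack:
    """Load the five canonical layers ``<name>.asc`` from a directory."""
    raster_dir = Path(raster_dir)
    overrides = dict(nodata_override or {})
    layers = {}
    for name in PREDICTORS:
        path = raster_dir / f"{name}{suffix}"
        if not path.exists():
            raise FileNotFoundError(f"predictor layer missing: {path}")
        layers[name] = read_ascii_grid(path, nodata_override=overrides.get(name))
    return PredictorStack(layers=layers)


def write_stack(stack: PredictorStack, raster_dir: str | Path, suffix: str = ".asc") -> None:
    raster_dir = Path(raster_dir)
    raster_dir.mkdir(parents=True, exist_ok=True)
    for name, raster in stack.layers.items():
        write_ascii_grid(raster, raster_dir / f"{name}{suffix}")
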