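"""Synthetic predictor stacks and locality tables with known structure.

Real socioeconomic surfaces (GDP, population density, deprivation, travel
times) are spatially smooth with large nodata regions (oceans, missing
states).  The generator emulates that shape: each predictor is a seeded sum
of Gaussian bumps standardized over valid cells, with nodata carved out in
contiguous blobs.  Locality Ho is generated phenomenologically — a linear
function of a chosen subset of predictors plus an island offset and Gaussian
noise, clipped to [0, 1] — so every downstream stage can be tested against a
known truth.  It is not a population-genetic simulator: Ho comes from the
stated regression function, not from drift or coalescent theory.

Default conditions mirror the compiled rat data: around 80 localities per
species, island fraction near 0.3, Ho centred near 0.55 with noise on the
scale of a few hundredths, and population density carrying the dominant
effect among the five predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import PREDICTORS, GridGeometry, PredictorStack, Raster
from .localities import LocalityRecord


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study condition.

    ``beta`` is in Ho units per standardized predictor unit, ordered as the
    canonical predictor names; ``island_effect`` is the additive Ho offset of
    island records.
    """

    seed: int = 0
    nrows: int = 90
    ncols: int = 180
    west: float = -180.0
    north: float = 90.0
    cellsize: float = 2.0          # degrees
    n_localities: int = 80
    beta: tuple[float, ...] = (0.03, 0.10, 0.03, 0.02, 0.03)
    intercept: float = 0.55
    noise_sd: float = 0.05
    nodata_fraction: float = 0.10
    island_fraction: float = 0.30
    island_effect: float = 0.05
    n_bumps: int = 10

    def __post_init__(self):
        if not (0 <= self.nodata_fraction < 1):
            raise ValueError("nodata_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.beta) != len(PREDICTORS):
            raise ValueError(f"beta needs {len(PREDICTORS)} entries")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            west=self.west, north=self.north,
            xres=self.cellsize, yres=self.cellsize,
            nrows=self.nrows, ncols=self.ncols,
        )


def _bump_field(rng: np.random.Generator, geom: GridGeometry, n_bumps: int) -> np.ndarray:
    lon = geom.lon_centers()
    lat = geom.lat_centers()
    lon2, lat2 = np.meshgrid(lon, lat)
    # bump widths of 2-10% of the extent: sub-continental structure, smooth
    # at the working resolution yet weakly correlated between layers
    extent = max(geom.east - geom.west, geom.north - geom.south)
    out = np.zeros(geom.shape)
    for _ in range(n_bumps):
        cx = rng.uniform(geom.west, geom.east)
        cy = rng.uniform(geom.south, geom.north)
        sigma = rng.uniform(0.02, 0.10) * extent
        amp = rng.uniform(-1.0, 1.0)
        out += amp * np.exp(-((lon2 - cx) ** 2 + (lat2 - cy) ** 2) / (2 * sigma**2))
    return out


def _nodata_blobs(rng: np.random.Generator, geom: GridGeometry, fraction: float) -> np.ndarray:
    """Boolean mask of contiguous circular nodata blobs covering ~fraction."""
    mask = np.zeros(geom.shape, dtype=bool)
    if fraction <= 0:
        return mask
    target = fraction * mask.size
    rows, cols = np.indices(geom.shape)
    guard = 0
    while mask.sum() < target and guard < 1000:
        guard += 1
        cr = rng.integers(0, geom.nrows)
        cc = rng.integers(0, geom.ncols)
        radius = rng.uniform(0.02, 0.12) * max(geom.nrows, geom.ncols)
        mask |= (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2
    return mask


def generate_stack(scenario: SyntheticScenario) -> PredictorStack:
    """Five smooth standardized predictor fields with nodata blobs.

    Deterministic given the scenario seed; with ``nodata_fraction=0`` every
    cell is valid.  Each layer is standardized to zero mean / unit variance
    over its valid cells.
    """
    geom = scenario.geometry
    if geom.nrows < 10 or geom.ncols < 10:
        raise ValueError("grid must be at least 10x10")
    rng = np.random.default_rng(scenario.seed)
    layers = {}
    for name in PREDICTORS:
        values = _bump_field(rng, geom, scenario.n_bumps)
        nodata = _nodata_blobs(rng, geom, scenario.nodata_fraction)
        values[nodata] = np.nan
        valid = np.isfinite(values)
        mu = values[valid].mean()
        sd = values[valid].std()
        if sd == 0:
            sd = 1.0
        values[valid] = (values[valid] - mu) / sd
        layers[name] = Raster(values=values, geometry=geom)
    return PredictorStack(layers=layers)


def generate_localities(
    scenario: SyntheticScenario,
    stack: PredictorStack,
    species: str = "rattus",
) -> list[LocalityRecord]:
    """Sample localities on valid cells with Ho from the known linear truth.

    Points sit at cell centers of cells valid in all five layers, drawn
    uniformly without replacement when possible.  Ho is

        clip(intercept + sum_v beta_v * x_v + island_effect * 1[island]
             + Normal(0, noise_sd), 0, 1)

    and an ``island_fraction`` share of records is labelled island.
    """
    geom = stack.geometry
    complete = stack.complete()
    valid_idx = np.flatnonzero(complete)
    if valid_idx.size == 0:
        raise ValueError("no valid cells to place localities on")
    rng = np.random.default_rng(np.random.SeedSequence((scenario.seed, 1)))
    n = scenario.n_localities
    replace = valid_idx.size < n
    chosen = rng.choice(valid_idx, size=n, replace=replace)
    rows, cols = np.unravel_index(chosen, geom.shape)
    lon, lat = geom.cell_center(rows, cols)
    X = stack.as_array()[:, rows, cols].T      # n x 5, standardized fields
    island = rng.random(n) < scenario.island_fraction
    noise = rng.normal(0.0, scenario.noise_sd, size=n)
    ho = (
        scenario.intercept
        + X @ np.asarray(scenario.beta)
        + scenario.island_effect * island
        + noise
    )
    ho = np.clip(ho, 0.0, 1.0)
    records = []
    for i in range(n):
        records.append(
            LocalityRecord(
                species=species,
                study_id="synthetic",
                site=f"loc{i:04d}",
                lon=float(lon[i]),
                lat=float(lat[i]),
                ho=float(ho[i]),
                insularity="island" if island[i] else "mainland",
                marker="microsatellite",
            )
        )
    return records
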