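"""Grid containers and the seven-class land-use codebook.

All rasters in this package are plain row-major numpy arrays with cell (0, 0)
at the north-west corner.  There is no real CRS: areas are always derived from
``cell_size_km**2``, never from projection math.  The exchange format is the
ESRI ASCII grid (.asc), which round-trips integer and float grids losslessly
at the precision we write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Land-use codebook: seven classes used throughout the pipeline.
FOREST, GRASSLAND, WATER, URBAN, UNUSED, PADDY, DRY = 1, 2, 3, 4, 5, 6, 7

CLASS_CODES = (FOREST, GRASSLAND, WATER, URBAN, UNUSED, PADDY, DRY)
CLASS_NAMES = {
    FOREST: "forest",
    GRASSLAND: "grassland",
    WATER: "water",
    URBAN: "urban_rural",
    UNUSED: "unused",
    PADDY: "paddy",
    DRY: "dry",
}
NAME_TO_CODE = {v: k for k, v in CLASS_NAMES.items()}

#: hm² per km² — carbon densities and ESV coefficients are quoted per hectare.
HM2_PER_KM2 = 100.0


@dataclass
class LandUseRaster:
    """Integer-coded categorical land-use grid for one year."""

    codes: np.ndarray
    cell_size_km: float = 1.0
    nodata: int = -1
    year: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("land-use grid must be 2-D")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("land-use grid must be integer-coded")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        bad = np.setdiff1d(np.unique(self.codes), list(CLASS_CODES) + [self.nodata])
        if bad.size:
            raise ValueError(f"unknown land-use code(s) {bad.tolist()} in raster")

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return self.codes != self.nodata

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def mask(self, code: int) -> np.ndarray:
        return self.codes == code


@dataclass
class ClimateStack:
    """Monthly + annual precipitation and annual reference evapotranspiration.

    ``monthly_precip`` has shape (12, rows, cols); ``annual_precip`` equals its
    sum over months by construction and is checked on creation.
    """

    monthly_precip: np.ndarray
    annual_pet: np.ndarray
    cell_size_km: float = 1.0

    annual_precip: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.monthly_precip = np.asarray(self.monthly_precip, dtype=float)
        self.annual_pet = np.asarray(self.annual_pet, dtype=float)
        if self.monthly_precip.ndim != 3 or self.monthly_precip.shape[0] != 12:
            raise ValueError("monthly_precip must have shape (12, rows, cols)")
        if np.any(self.monthly_precip < 0) or np.any(self.annual_pet < 0):
            raise ValueError("precipitation and PET must be non-negative")
        self.annual_precip = self.monthly_precip.sum(axis=0)


@dataclass
class SoilTerrainStack:
    """Soil erodibility K, slope-length-steepness LS, plant-available water fraction."""

    k_factor: np.ndarray
    ls_factor: np.ndarray
    pawc: np.ndarray

    def __post_init__(self) -> None:
        self.k_factor = np.asarray(self.k_factor, dtype=float)
        self.ls_factor = np.asarray(self.ls_factor, dtype=float)
        self.pawc = np.asarray(self.pawc, dtype=float)
        if np.any(self.k_factor < 0) or np.any(self.ls_factor < 0):
            raise ValueError("K and LS must be non-negative")
        if np.any((self.pawc < 0) | (self.pawc > 1)):
            raise ValueError("PAWC must lie in [0, 1]")


@dataclass
class RegionPartition:
    """Exhaustive partition of the grid into contiguous integer-labelled regions."""

    region_id: np.ndarray
    cell_size_km: float = 1.0

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id)
        if not np.issubdtype(self.region_id.dtype, np.integer):
            raise ValueError("region ids must be integers")

    @property
    def labels(self) -> np.ndarray:
        return np.unique(self.region_id)


def write_ascii_grid(grid: np.ndarray, path: str | Path, cell_size_km: float = 1.0,
                     nodata: float = -9999) -> None:
    """Write a 2-D grid as an ESRI ASCII raster."""
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("only 2-D grids can be written")
    path = Path(path)
    is_int = np.issubdtype(grid.dtype, np.integer)
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {cell_size_km}\n"
        f"NODATA_value {int(nodata) if is_int else nodata}\n"
    )
    fmt = "%d" if is_int else "%.10g"
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Read an ESRI ASCII raster; returns (grid, cell_size, nodata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            line = fh.readline().split()
            if len(line) != 2:
                raise ValueError(f"unparseable ASCII grid header in {path}")
            header[line[0].lower()] = float(line[1])
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (nrows, ncols):
        raise ValueError(
            f"grid shape {body.shape} does not match header ({nrows}, {ncols}) in {path}")
    if np.allclose(body, np.round(body)):
        body = body.astype(np.int64)
    return body, header["cellsize"], header.get("nodata_value", -9999)
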