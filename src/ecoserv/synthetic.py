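"""Seeded synthetic landscapes emulating the study region's data structure.

The generators produce the four raster inputs the service models consume —
a seven-class land-use grid with spatially autocorrelated patches, a monthly
climate stack with a south-to-north precipitation gradient, soil/terrain
factor grids, and a contiguous region (city/county) partition — plus a
tabular panel generator with planted linear effects for exercising the
statistics layer in isolation.

Every generator is a pure function of (spec, seed): identical inputs give
bit-identical outputs, and no global random state is touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import (CLASS_NAMES, NAME_TO_CODE, ClimateStack, LandUseRaster,
                    RegionPartition, SoilTerrainStack)

log = logging.getLogger(__name__)

#: Land-use shares for the study region's base year (areas of the seven
#: classes in 1990, normalised).  Cropland (dry + paddy) dominates.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "forest": 0.0905, "grassland": 0.0421, "water": 0.0492,
    "urban_rural": 0.1168, "unused": 0.0028, "paddy": 0.1972, "dry": 0.5014,
}

#: Per-decade conversion rules reproducing the dominant observed dynamic:
#: urban expansion onto cropland, grassland loss to dry land, modest water
#: expansion, near-disappearance of unused land, near-stable forest.
DEFAULT_CHANGE_RULES: list[tuple[str, str, float]] = [
    ("dry", "urban_rural", 0.018),
    ("paddy", "urban_rural", 0.012),
    ("grassland", "dry", 0.095),
    ("paddy", "water", 0.0045),
    ("unused", "dry", 0.25),
    ("forest", "urban_rural", 0.0005),
]

#: Monthly share of annual precipitation: monsoonal profile with a wet
#: summer (>50% of the annual total in June–September), so the erosivity
#: formula sees a realistic monthly concentration.
DEFAULT_SEASONAL_PROFILE = np.array(
    [0.02, 0.03, 0.05, 0.07, 0.09, 0.13, 0.18, 0.15, 0.10, 0.08, 0.06, 0.04])


@dataclass
class LandscapeSpec:
    """Full description of one synthetic landscape realisation."""

    grid_rows: int = 120
    grid_cols: int = 120
    cell_size_km: float = 1.0
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    n_regions: int = 29
    precip_mean_mm: float = 992.9
    precip_gradient: float = 2.0     # mm per row, increasing southwards
    pet_mean_mm: float = 1000.0
    seasonal_profile: np.ndarray = field(
        default_factory=lambda: DEFAULT_SEASONAL_PROFILE.copy())
    years: tuple[str, ...] = ("1990", "2000", "2010", "2020")
    change_rules: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_CHANGE_RULES))
    patch_scale: float = 4.0         # Gaussian smoothing radius, cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_km <= 0:
            raise ValueError("cell size must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"class proportions must sum to 1 (got {total:.12f})")
        if any(not (0 <= p <= 1) for p in self.class_proportions.values()):
            raise ValueError("class proportions must lie in [0, 1]")
        unknown = set(self.class_proportions) - set(NAME_TO_CODE)
        if unknown:
            raise ValueError(f"unknown class name(s) {sorted(unknown)}")
        if self.n_regions <= 0 or self.n_regions > self.grid_rows * self.grid_cols:
            raise ValueError("n_regions must be in [1, number of cells]")
        profile = np.asarray(self.seasonal_profile, dtype=float)
        if profile.shape != (12,) or abs(profile.sum() - 1.0) > 1e-9:
            raise ValueError("seasonal profile must be 12 non-negative shares summing to 1")

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standard-normal white noise smoothed to an autocorrelated field."""
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                   mode="wrap")


def generate_landuse(spec: LandscapeSpec, seed: int | None = None,
                     year: str | None = None) -> LandUseRaster:
    """Generate a categorical land-use raster with controlled proportions.

    One smoothed Gaussian field is drawn per class; cells are assigned
    greedily, class by class, each class claiming its target number of
    still-unassigned cells in decreasing order of its own field.  This keeps
    patches contiguous (the field is autocorrelated) while pinning realized
    proportions to the requested ones up to integer rounding.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = (spec.grid_rows, spec.grid_cols)
    names = [n for n in CLASS_NAMES.values() if spec.class_proportions.get(n, 0) > 0]
    fields = {n: _smooth_noise(rng, shape, spec.patch_scale) for n in names}

    # integer target counts; distribute rounding remainder to largest classes
    raw = {n: spec.class_proportions[n] * spec.n_cells for n in names}
    counts = {n: int(np.floor(raw[n])) for n in names}
    short = spec.n_cells - sum(counts.values())
    for n in sorted(names, key=lambda n: raw[n] - counts[n], reverse=True)[:short]:
        counts[n] += 1

    codes = np.full(shape, -1, dtype=np.int64)
    unassigned = np.ones(shape, dtype=bool)
    # assign rarest classes first so their patches are not pre-empted
    for n in sorted(names, key=lambda n: counts[n]):
        f = np.where(unassigned, fields[n], -np.inf)
        flat_idx = np.argpartition(f.ravel(), -counts[n])[-counts[n]:]
        codes.ravel()[flat_idx] = NAME_TO_CODE[n]
        unassigned.ravel()[flat_idx] = False
    assert not unassigned.any()
    return LandUseRaster(codes, cell_size_km=spec.cell_size_km,
                         year=year or (spec.years[0] if spec.years else ""))


def advance_landuse(base: LandUseRaster,
                    change_rules: list[tuple[str, str, float]],
                    seed: int, year: str = "") -> LandUseRaster:
    """Apply per-step conversion rules, preferring cells near the target class.

    Each rule (from_class, to_class, fraction) converts ``round(fraction ×
    current from-class count)`` cells, chosen in increasing order of distance
    to the nearest existing target-class cell (seeded random tie-breaks), so
    growth accretes onto existing patches the way urban expansion does.
    """
    rng = np.random.default_rng(seed)
    codes = base.codes.copy()
    for from_name, to_name, frac in change_rules:
        if from_name not in NAME_TO_CODE or to_name not in NAME_TO_CODE:
            raise ValueError(f"change rule references unknown class: "
                             f"{from_name!r} -> {to_name!r}")
        if frac < 0:
            raise ValueError("conversion fraction must be non-negative")
        from_code, to_code = NAME_TO_CODE[from_name], NAME_TO_CODE[to_name]
        src = np.flatnonzero(codes == from_code)
        n_convert = int(round(frac * src.size))
        if n_convert > src.size:
            log.warning("rule %s->%s requests %d cells but only %d available; "
                        "converting all", from_name, to_name, n_convert, src.size)
            n_convert = src.size
        if n_convert == 0:
            continue
        target_mask = codes == to_code
        if target_mask.any():
            dist = ndimage.distance_transform_edt(~target_mask).ravel()[src]
        else:
            dist = np.zeros(src.size)
        order = np.lexsort((rng.random(src.size), dist))
        codes.ravel()[src[order[:n_convert]]] = to_code
    return LandUseRaster(codes, cell_size_km=base.cell_size_km,
                         nodata=base.nodata, year=year)


def landuse_series(spec: LandscapeSpec) -> dict[str, LandUseRaster]:
    """Base-year landscape plus one advance step per subsequent year."""
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(spec.years))]
    out = {spec.years[0]: generate_landuse(spec, seed=seeds[0], year=spec.years[0])}
    current = out[spec.years[0]]
    for i, year in enumerate(spec.years[1:], start=1):
        current = advance_landuse(current, spec.change_rules, seeds[i], year=year)
        out[year] = current
    return out


def generate_climate(spec: LandscapeSpec, seed: int | None = None,
                     precip_mean_mm: float | None = None) -> ClimateStack:
    """Monthly precipitation + annual PET with a linear north–south gradient.

    Annual precipitation increases southwards (down rows) at
    ``spec.precip_gradient`` mm/row, centred so that the domain mean equals
    ``precip_mean_mm`` exactly; the field is deterministic given the spec
    (one representative year per epoch, not a stochastic weather draw).
    Months split the annual total by the (wet-summer) seasonal profile.
    PET runs weakly opposite to the precipitation trend, as in the region's
    energy-limited south / water-limited north contrast.
    """
    if spec.grid_rows <= 0 or spec.grid_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    mean = spec.precip_mean_mm if precip_mean_mm is None else precip_mean_mm
    rows = np.arange(spec.grid_rows, dtype=float)
    trend = mean + spec.precip_gradient * (rows - rows.mean())
    annual = np.clip(np.tile(trend[:, None], (1, spec.grid_cols)), 0.0, None)
    monthly = np.asarray(spec.seasonal_profile)[:, None, None] * annual[None, :, :]
    pet = np.clip(spec.pet_mean_mm - 0.2 * (annual - mean), 0.0, None)
    return ClimateStack(monthly, pet, cell_size_km=spec.cell_size_km)


def generate_soil_terrain(spec: LandscapeSpec, seed: int | None = None) -> SoilTerrainStack:
    """Smooth positive K/LS fields and a PAWC fraction field.

    Magnitudes sit in ranges typical of regional USLE and Budyko inputs:
    K around 0.03 t·h/(MJ·mm), LS around 1.5 (flat plain with low-relief
    uplands), PAWC around 0.12 of soil volume.
    """
    if spec.grid_rows <= 0 or spec.grid_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    shape = (spec.grid_rows, spec.grid_cols)
    k = 0.03 * np.exp(0.3 * _smooth_noise(rng, shape, spec.patch_scale))
    ls = 1.5 * np.exp(0.8 * _smooth_noise(rng, shape, spec.patch_scale))
    pawc = np.clip(0.12 + 0.4 * _smooth_noise(rng, shape, spec.patch_scale), 0.01, 0.35)
    return SoilTerrainStack(k, ls, pawc)


def generate_regions(spec: LandscapeSpec, seed: int | None = None) -> RegionPartition:
    """Partition the grid into ``n_regions`` contiguous regions.

    Nearest-seed tessellation: n seed cells are drawn uniformly without
    replacement and every cell is labelled by its (Euclidean-)nearest seed.
    Cells of such a tessellation form star-convex, hence contiguous, regions,
    and the partition is exhaustive by construction.
    """
    if spec.n_regions > spec.n_cells:
        raise ValueError("more regions than cells")
    rng = np.random.default_rng(spec.seed + 3 if seed is None else seed)
    shape = (spec.grid_rows, spec.grid_cols)
    flat = rng.choice(spec.n_cells, size=spec.n_regions, replace=False)
    seed_mask = np.zeros(shape, dtype=bool)
    seed_mask.ravel()[flat] = True
    _, (ri, ci) = ndimage.distance_transform_edt(~seed_mask, return_indices=True)
    label_of_seed = np.full(shape, -1, dtype=np.int64)
    label_of_seed.ravel()[flat] = np.arange(spec.n_regions)
    region_id = label_of_seed[ri, ci]
    return RegionPartition(region_id, cell_size_km=spec.cell_size_km)


def morans_i(indicator: np.ndarray) -> float:
    """Moran's I of a binary indicator on the 4-neighbour lattice (rook moves)."""
    z = indicator.astype(float) - indicator.mean()
    num = (z[:-1, :] * z[1:, :]).sum() + (z[:, :-1] * z[:, 1:]).sum()
    w_total = 2 * (z.shape[0] - 1) * z.shape[1] + 2 * z.shape[0] * (z.shape[1] - 1)
    denom = (z**2).sum()
    if denom == 0:
        return 0.0
    return float((z.size / w_total) * (2 * num) / denom)


def synthetic_service_panel(coefficients: pd.DataFrame,
                            n_regions: int = 29,
                            years: tuple[str, ...] = ("1990", "2000", "2010", "2020"),
                            noise_sd: float | dict[str, float] = 0.0,
                            seed: int = 0,
                            concentration: float = 8.0,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular panel with services planted as linear functions of proportions.

    ``coefficients``: rows = service names, columns = class names (plus an
    optional ``intercept`` column).  Proportions are drawn from a Dirichlet
    centred on the regional base-year shares; each service value is
    intercept + Σ coef·proportion + N(0, noise_sd).  Returns
    (panel, proportions), both indexed by (region, year).
    """
    rng = np.random.default_rng(seed)
    base = np.array([DEFAULT_PROPORTIONS[n] for n in CLASS_NAMES.values()])
    idx = pd.MultiIndex.from_product([range(n_regions), years],
                                     names=["region", "year"])
    props = pd.DataFrame(
        rng.dirichlet(base * concentration, size=len(idx)),
        index=idx, columns=list(CLASS_NAMES.values()))
    panel = pd.DataFrame(index=idx)
    for service, row in coefficients.iterrows():
        sd = noise_sd.get(service, 0.0) if isinstance(noise_sd, dict) else noise_sd
        y = np.full(len(idx), float(row.get("intercept", 0.0)))
        for cls in CLASS_NAMES.values():
            if cls in row.index:
                y = y + float(row[cls]) * props[cls].to_numpy()
        panel[service] = y + rng.normal(0.0, sd, size=len(idx))
    return panel, props
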