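"""Region × year × service panel — the bridge from rasters to statistics.

Extensive services (carbon, water volume, erosion tonnage, provisioning
value) are summed within regions; habitat quality, an intensive index, is
averaged (area-weighted, i.e. a plain cell mean on a uniform grid).  Each
total carries a parallel per-unit-area column:

    carbon_t_hm2              t/hm²
    water_yield_mm            mm of runoff depth
    erosion_t_km2             t/km²
    food_material_1e4yuan_km2 10⁴ Yuan/km²
    habitat_quality           (already per-cell; repeated as its own density)

so per-unit × area reproduces the total exactly under the unit conversions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import CLASS_CODES, CLASS_NAMES, HM2_PER_KM2, LandUseRaster, RegionPartition

log = logging.getLogger(__name__)

SERVICE_COLUMNS = ("carbon_1e8t", "habitat_quality", "water_yield_1e8m3",
                   "erosion_1e4t", "food_material_1e8yuan")
PER_UNIT_COLUMNS = ("carbon_t_hm2", "habitat_quality", "water_yield_mm",
                    "erosion_t_km2", "food_material_1e4yuan_km2")


def zonal_totals(carbon_t: np.ndarray, quality: np.ndarray, yield_mm: np.ndarray,
                 loss_t: np.ndarray, value_yuan: np.ndarray,
                 lu: LandUseRaster, regions: RegionPartition,
                 year: str) -> pd.DataFrame:
    """One panel row per region for one year (totals and per-unit-area)."""
    rows = []
    cell_area = lu.cell_area_km2
    for label in regions.labels:
        m = (regions.region_id == label) & lu.valid
        if not m.any():
            log.warning("region %s empty in %s; row skipped", label, year)
            continue
        area_km2 = float(m.sum()) * cell_area
        carbon_t_total = float(carbon_t[m].sum())
        water_m3 = float(yield_mm[m].sum()) * cell_area * 1e3
        erosion_t = float(loss_t[m].sum())
        value = float(value_yuan[m].sum())
        rows.append({
            "region": int(label), "year": year, "area_km2": area_km2,
            "carbon_1e8t": carbon_t_total / 1e8,
            "habitat_quality": float(quality[m].mean()),
            "water_yield_1e8m3": water_m3 / 1e8,
            "erosion_1e4t": erosion_t / 1e4,
            "food_material_1e8yuan": value / 1e8,
            "carbon_t_hm2": carbon_t_total / (area_km2 * HM2_PER_KM2),
            "water_yield_mm": water_m3 / (area_km2 * 1e6) * 1e3,
            "erosion_t_km2": erosion_t / area_km2,
            "food_material_1e4yuan_km2": value / area_km2 / 1e4,
        })
    return pd.DataFrame(rows).set_index(["region", "year"])


def landuse_proportions(lu: LandUseRaster, regions: RegionPartition,
                        year: str) -> pd.DataFrame:
    """Fraction of each class per region; rows sum to 1."""
    rows = []
    for label in regions.labels:
        m = (regions.region_id == label) & lu.valid
        n = m.sum()
        if n == 0:
            continue
        row = {"region": int(label), "year": year}
        for code in CLASS_CODES:
            row[CLASS_NAMES[code]] = float((lu.codes[m] == code).sum()) / n
        rows.append(row)
    return pd.DataFrame(rows).set_index(["region", "year"])


def service_change(t0: pd.Series | pd.DataFrame, t1: pd.Series | pd.DataFrame
                   ) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Absolute and percent change between two service tables.

    Accepts per-class Series (one service) or DataFrames with one column per
    service; percent change is NaN where the earlier value is zero.
    """
    from .accounting import change_stats
    if isinstance(t0, pd.Series):
        return change_stats(t0, t1)
    return {col: change_stats(t0[col], t1[col]) for col in t0.columns}


def panel_service_change(panel: pd.DataFrame, y0: str, y1: str) -> pd.DataFrame:
    """Domain-level change of every service column between two panel years."""
    for y in (y0, y1):
        if y not in panel.index.get_level_values("year"):
            raise ValueError(f"year {y!r} missing from panel")
    agg = {c: "sum" for c in SERVICE_COLUMNS if c != "habitat_quality"}
    by_year = panel.groupby(level="year").agg(agg)
    # domain habitat quality: area-weighted mean across regions
    w = panel["area_km2"]
    hq = (panel["habitat_quality"] * w).groupby(level="year").sum() / \
        w.groupby(level="year").sum()
    by_year["habitat_quality"] = hq
    v0, v1 = by_year.loc[y0], by_year.loc[y1]
    absolute = v1 - v0
    pct = pd.Series(np.where(v0 == 0, np.nan, 100.0 * absolute / v0), index=v0.index)
    return pd.DataFrame({y0: v0, y1: v1, "abs_change": absolute, "pct_change": pct})
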