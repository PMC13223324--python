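"""Per-class biophysical parameter tables and their validated loaders.

Each table ships as a CSV fixture transcribed from published per-class values
for a seven-class land-use legend (carbon pool densities; crop coefficients
and rooting depths; USLE cover and practice factors; habitat-threat weights,
impact distances and sensitivities; provisioning-value coefficients).  Loaders
validate coverage of all seven classes and the documented value ranges at read
time, so a malformed table fails loudly at the door rather than deep in a
raster loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .grids import CLASS_NAMES, NAME_TO_CODE

_REQUIRED_CLASSES = set(CLASS_NAMES.values())


def _read_fixture(name: str, path: str | Path | None) -> pd.DataFrame:
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"parameter table not found: {p}")
        return pd.read_csv(p)
    with resources.files("ecoserv.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _check_classes(df: pd.DataFrame, table: str, column: str = "class") -> None:
    seen = set(df[column])
    unknown = seen - _REQUIRED_CLASSES
    if unknown:
        raise ValueError(f"{table}: unknown class name(s) {sorted(unknown)}")
    missing = _REQUIRED_CLASSES - seen
    if missing:
        raise ValueError(f"{table}: missing class row(s) {sorted(missing)}")


@dataclass
class CarbonDensityRecord:
    """Four carbon pools (t/hm²) per land-use class."""

    pools: pd.DataFrame  # index: class name; columns c_above..c_dead

    def __post_init__(self) -> None:
        if (self.pools[["c_above", "c_below", "c_soil", "c_dead"]] < 0).any().any():
            raise ValueError("carbon pool densities must be non-negative")

    def total_density(self, class_name: str) -> float:
        """Total carbon density C_above + C_below + C_soil + C_dead (t/hm²)."""
        if class_name not in self.pools.index:
            raise KeyError(f"no carbon density row for class {class_name!r}")
        row = self.pools.loc[class_name]
        return float(row.c_above + row.c_below + row.c_soil + row.c_dead)


@dataclass
class WaterYieldParams:
    """Per-class crop coefficient and rooting depth plus Budyko globals.

    ``z_coeff`` is the Zhang/Fu seasonality constant; ``omega_offset`` the
    additive floor of the ω parameter (ω = Z·AWC/P + offset).
    """

    kc: dict[str, float]
    root_depth_mm: dict[str, float]
    z_coeff: float = 5.0
    omega_offset: float = 1.25

    def __post_init__(self) -> None:
        if self.z_coeff <= 0:
            raise ValueError("seasonality constant Z must be positive")
        if any(v < 0 for v in self.kc.values()):
            raise ValueError("crop coefficients must be non-negative")
        if any(v < 0 for v in self.root_depth_mm.values()):
            raise ValueError("root depths must be non-negative")


@dataclass
class UsleClassFactors:
    """USLE cover (C) and support-practice (P) factors per land-use class."""

    c_factor: dict[str, float]
    p_factor: dict[str, float]

    def __post_init__(self) -> None:
        for name, d in (("C", self.c_factor), ("P", self.p_factor)):
            if any(not (0 <= v <= 1) for v in d.values()):
                raise ValueError(f"USLE {name} factors must lie in [0, 1]")


@dataclass
class ThreatRecord:
    """Habitat threat sources: weight, maximum impact distance, decay kind."""

    table: pd.DataFrame  # index: threat class name; weight, max_distance_km, decay

    def __post_init__(self) -> None:
        if not ((self.table.weight > 0) & (self.table.weight <= 1)).all():
            raise ValueError("threat weights must lie in (0, 1]")
        if not (self.table.max_distance_km > 0).all():
            raise ValueError("threat max distances must be positive")
        bad = set(self.table.decay) - {"linear", "exponential"}
        if bad:
            raise ValueError(f"unknown decay kind(s) {sorted(bad)}")


@dataclass
class SensitivityRecord:
    """Habitat suitability H_j and sensitivity S_jr of each class to each threat."""

    table: pd.DataFrame  # index: class name; suitability + one column per threat

    def __post_init__(self) -> None:
        if ((self.table < 0) | (self.table > 1)).any().any():
            raise ValueError("suitability and sensitivities must lie in [0, 1]")

    def suitability(self, class_name: str) -> float:
        return float(self.table.loc[class_name, "suitability"])


@dataclass
class EsvCoefficients:
    """Provisioning-service value coefficients (Yuan/hm²/yr) per class.

    The combined food+raw-material coefficient is the sum of the two
    components; the printed combined row (which differs by ±1 Yuan from the
    component sums for two classes due to rounding) is retained alongside.
    """

    table: pd.DataFrame  # index: class; food_production, raw_material, combined_printed
    unit_value: float = 1505.8  # Yuan/hm² per dimensionless equivalent

    def __post_init__(self) -> None:
        if (self.table[["food_production", "raw_material"]] < 0).any().any():
            raise ValueError("ESV coefficients must be non-negative")

    def combined(self, use_printed: bool = False) -> pd.Series:
        if use_printed:
            return self.table["combined_printed"].astype(float)
        return (self.table["food_production"] + self.table["raw_material"]).astype(float)


# ---------------------------------------------------------------------------
# loaders

def load_carbon_density(path: str | Path | None = None) -> CarbonDensityRecord:
    df = _read_fixture("carbon_density.csv", path)
    _check_classes(df, "carbon_density")
    return CarbonDensityRecord(df.set_index("class"))


def load_landuse_attributes(path: str | Path | None = None,
                            z_coeff: float = 5.0,
                            omega_offset: float = 1.25,
                            ) -> tuple[WaterYieldParams, UsleClassFactors]:
    """Load the joint crop-coefficient / rooting-depth / C / P table."""
    df = _read_fixture("landuse_attributes.csv", path)
    _check_classes(df, "landuse_attributes")
    df = df.set_index("class")
    wy = WaterYieldParams(kc=df["kc"].to_dict(),
                          root_depth_mm=df["root_depth_mm"].astype(float).to_dict(),
                          z_coeff=z_coeff, omega_offset=omega_offset)
    usle = UsleClassFactors(c_factor=df["c_factor"].to_dict(),
                            p_factor=df["p_factor"].to_dict())
    return wy, usle


def load_threats(path: str | Path | None = None) -> ThreatRecord:
    df = _read_fixture("threats.csv", path)
    unknown = set(df["threat"]) - _REQUIRED_CLASSES
    if unknown:
        raise ValueError(f"threats: unknown class name(s) {sorted(unknown)}")
    return ThreatRecord(df.set_index("threat"))


def load_sensitivity(path: str | Path | None = None) -> SensitivityRecord:
    df = _read_fixture("sensitivity.csv", path)
    _check_classes(df, "sensitivity")
    return SensitivityRecord(df.set_index("class"))


def load_esv_coefficients(path: str | Path | None = None,
                          unit_value: float = 1505.8) -> EsvCoefficients:
    df = _read_fixture("esv_coefficients.csv", path)
    _check_classes(df, "esv_coefficients")
    return EsvCoefficients(df.set_index("class"), unit_value=unit_value)


def load_printed_service_totals(path: str | Path | None = None) -> pd.DataFrame:
    """Published per-class service totals for the two bracketing years."""
    df = _read_fixture("printed_service_totals.csv", path)
    return df.set_index(["service", "row"])


def load_printed_transfer_summary(path: str | Path | None = None) -> pd.DataFrame:
    """Published land-use area marginals for 1990/2020 with change rows."""
    df = _read_fixture("printed_transfer_summary.csv", path)
    _check_classes(df, "printed_transfer_summary")
    return df.set_index("class")


def class_lookup_grid(codes, mapping: dict[str, float], nodata_fill: float = 0.0):
    """Map a class-name→value dict over an integer-coded grid."""
    import numpy as np

    out = np.full(codes.shape, nodata_fill, dtype=float)
    for name, value in mapping.items():
        out[codes == NAME_TO_CODE[name]] = value
    return out
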