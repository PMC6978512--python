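"""Electricity-potential and carbon-mass conversions for woody feedstock.

Conversions are linear in biomass.  Conventional boiler plants convert
roughly one bone-dry ton (BDT) per MWh of electricity; small-scale
gasifier-generator systems need about 4.7 BDT/MWh.  These are treated as
cited industry constants, not derived from calorific values.  Carbon mass
uses 907.18474 kg per BDT (2000 lb at 0 % moisture) and a wood carbon
fraction defaulting to 0.47.

Supply-years arithmetic and radius queries support siting questions such
as "how long could a 50 MW plant at 80 % capacity factor run on the
feasible feedstock of a zone" and "how much feedstock lies within 30 km
of an existing facility".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnergyParams",
    "CarbonParams",
    "bdt_to_mwh",
    "annual_generation_twh",
    "years_of_supply",
    "facility_radius_feedstock",
    "bdt_to_tg_carbon",
]

HOURS_PER_YEAR = 8760.0


@dataclass(frozen=True)
class EnergyParams:
    bdt_per_mwh_boiler: float = 1.0
    bdt_per_mwh_gasifier: float = 4.7
    capacity_factor: float = 0.80
    plant_mw: float = 50.0
    annual_generation_override_twh: float | None = None

    def __post_init__(self) -> None:
        if self.bdt_per_mwh_boiler <= 0 or self.bdt_per_mwh_gasifier <= 0:
            raise ValueError("conversion factors must be positive")
        if not 0.0 < self.capacity_factor <= 1.0:
            raise ValueError("capacity_factor must be in (0, 1]")
        if self.plant_mw <= 0:
            raise ValueError("plant_mw must be positive")

    def bdt_per_mwh(self, technology: str) -> float:
        if technology == "boiler":
            return self.bdt_per_mwh_boiler
        if technology == "gasifier":
            return self.bdt_per_mwh_gasifier
        raise ValueError(f"unknown technology {technology!r}")


@dataclass(frozen=True)
class CarbonParams:
    kg_per_bdt: float = 907.18474  # 2000 lb
    carbon_fraction: float = 0.47

    def __post_init__(self) -> None:
        if self.kg_per_bdt <= 0:
            raise ValueError("kg_per_bdt must be positive")
        if not 0.0 < self.carbon_fraction < 1.0:
            raise ValueError("carbon_fraction must be in (0, 1)")


def bdt_to_mwh(biomass_bdt: float, params: EnergyParams, technology: str = "boiler") -> float:
    """Electricity (MWh) from burning/gasifying ``biomass_bdt`` bone-dry tons."""
    if biomass_bdt < 0:
        raise ValueError("biomass must be >= 0")
    return biomass_bdt / params.bdt_per_mwh(technology)


def annual_generation_twh(params: EnergyParams) -> float:
    """Annual plant output in TWh: MW x 8760 h x capacity factor.

    An explicit override (``annual_generation_override_twh``) wins when
    set, for reproducing published round figures.  The unrounded value is
    returned; rounding belongs to the report layer.
    """
    if params.annual_generation_override_twh is not None:
        return params.annual_generation_override_twh
    return params.plant_mw * HOURS_PER_YEAR * params.capacity_factor / 1e6


def years_of_supply(
    biomass_bdt: float,
    annual_twh: float,
    params: EnergyParams,
    technology: str = "boiler",
) -> int:
    """Whole years a plant generating ``annual_twh`` can run on the feedstock.

    Annual demand is ``annual_twh`` x 1e6 MWh x the technology's BDT/MWh;
    the ratio is rounded to the nearest integer, halves away from zero.
    """
    if annual_twh <= 0:
        raise ValueError("annual generation must be positive")
    demand_bdt_per_year = annual_twh * 1e6 * params.bdt_per_mwh(technology)
    years = biomass_bdt / demand_bdt_per_year
    return int(np.floor(years + 0.5))  # half away from zero (biomass >= 0)


def facility_radius_feedstock(
    table: pd.DataFrame, site_x: float, site_y: float, radii_m: list[float]
) -> pd.DataFrame:
    """Feasible and cost-effective biomass within each radius of a site.

    Pixel membership is by center distance (Euclidean); nested radii give
    non-decreasing totals.  ``table`` is the per-pixel feedstock table.
    """
    dist = np.hypot(table["x"].to_numpy() - site_x, table["y"].to_numpy() - site_y)
    ce = table["cost_effective"].to_numpy()
    up = table["tdbm_upper"].to_numpy()
    lo = table["tdbm_lower"].to_numpy()
    records = []
    for radius in radii_m:
        within = dist <= radius
        records.append(
            {
                "radius_m": float(radius),
                "feasible_upper_bdt": float(up[within].sum()),
                "feasible_lower_bdt": float(lo[within].sum()),
                "cost_effective_upper_bdt": float(up[within & ce].sum()),
                "cost_effective_lower_bdt": float(lo[within & ce].sum()),
            }
        )
    return pd.DataFrame(records)


def bdt_to_tg_carbon(biomass_bdt: float, params: CarbonParams | None = None) -> float:
    """Carbon mass (Tg C) held in ``biomass_bdt`` bone-dry tons of wood."""
    if params is None:
        params = CarbonParams()
    if biomass_bdt < 0:
        raise ValueError("biomass must be >= 0")
    return biomass_bdt * params.kg_per_bdt * params.carbon_fraction / 1e9
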