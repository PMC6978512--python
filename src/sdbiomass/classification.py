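"""Harvest-cost classification of feasible dead-biomass pixels.

Feasible pixels (those surviving the isolation/wilderness/size/density
screens) are labeled along four independent cost dimensions:

* **Tree size** — mean volume per tree (VPT): <= 2.26 m^3 can be chipped
  on site (``onsite_chippable``); between 2.26 and 11.32 m^3 must be
  hauled to a facility chipper (``facility_only``).
* **Terrain slope** — percent slope from Horn's 3x3 gradient of the DEM:
  < 30 % allows ground-based harvest systems; 30-40 % is transitional
  (ground or cable); > 40 % requires cable or helicopter yarding.
* **Road access** — straight-line distance from pixel center to the
  nearest road, cut at 2000 m (the upper end of cable yarding distances);
  equivalently, membership in a 2000-m road buffer.
* **High Hazard Zone** — tier 1 and tier 2 membership (tiers may overlap)
  and county.

The *cost-effective* subset is VPT <= 2.26 AND slope < 40 AND road
distance <= 2000 m.  Boundary conventions: VPT exactly 2.26 counts as
on-site chippable; slope exactly 30 is transitional; slope exactly 40 is
cable/helicopter (and not cost-effective); road distance exactly 2000 m
counts as near.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .allocation import DeadBiomassGrid
from .geodata import GridAlignmentError, RoadNetwork, ZoneSet, distance_to_nearest_road

__all__ = [
    "VPT_ONSITE",
    "SLOPE_GROUND",
    "SLOPE_CABLE",
    "ROAD_CUTOFF_M",
    "slope_percent",
    "classify_pixels",
    "summarize",
]

log = logging.getLogger(__name__)

VPT_ONSITE = 2.26  # m^3/tree, on-site chipping limit
SLOPE_GROUND = 30.0  # % slope, below which ground-based systems operate
SLOPE_CABLE = 40.0  # % slope, above which cable/helicopter yarding is required
ROAD_CUTOFF_M = 2000.0


def slope_percent(dem: np.ndarray, pixel_size: float) -> np.ndarray:
    """Percent slope (100 x rise/run) from Horn's 3x3 finite differences.

    Edge pixels use clamped (edge-replicated) neighborhoods, so a plane's
    interior slope is exact while its outermost ring is attenuated in the
    direction normal to the edge.
    """
    dem = np.asarray(dem, dtype=float)
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8.0 * pixel_size)
    # row index increases southwards, so +y (north) is -row
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float) / (8.0 * pixel_size)
    gx = ndimage.correlate(dem, kx, mode="nearest")
    gy = ndimage.correlate(dem, ky, mode="nearest")
    return 100.0 * np.hypot(gx, gy)


def _vpt_class(vpt: np.ndarray) -> np.ndarray:
    return np.where(vpt <= VPT_ONSITE, "onsite_chippable", "facility_only")


def _slope_class(slope: np.ndarray) -> np.ndarray:
    out = np.full(slope.shape, "transitional", dtype=object)
    out[slope < SLOPE_GROUND] = "ground"
    out[slope >= SLOPE_CABLE] = "cable_heli"
    return out.astype(str)


def classify_pixels(
    upper: DeadBiomassGrid,
    lower: DeadBiomassGrid,
    vpt: np.ndarray,
    slope: np.ndarray,
    roads: RoadNetwork,
    zones: ZoneSet,
    vpt_onsite: float = VPT_ONSITE,
    slope_cable: float = SLOPE_CABLE,
    road_cutoff_m: float = ROAD_CUTOFF_M,
) -> pd.DataFrame:
    """Build the per-pixel feedstock table for all retained pixels.

    Each pixel that carries feasible biomass in either bound variant
    appears exactly once, with its coordinates, biomass bounds, class
    labels and the cost-effective flag.  Pixels in no county are labeled
    ``"none"`` (and logged); county summary tables skip them.
    """
    if upper.spec != lower.spec:
        raise GridAlignmentError("bound variants are on different grids")
    spec = upper.spec
    if slope.shape != spec.shape or vpt.shape != spec.shape:
        raise GridAlignmentError("slope/VPT raster not on the analysis grid")
    rows, cols = np.nonzero((upper.tdbm > 0) | (lower.tdbm > 0))
    x, y = spec.center_of(rows, cols)
    vpt_px = vpt[rows, cols]
    slope_px = slope[rows, cols]
    road_dist = distance_to_nearest_road(x, y, roads)

    def member(polys) -> np.ndarray:
        if not polys:
            return np.zeros(rows.size, dtype=bool)
        return shapely.intersects_xy(shapely.union_all(list(polys)), x, y)

    tier1 = member(zones.hhz_tier1)
    tier2 = member(zones.hhz_tier2)
    county = np.full(rows.size, "none", dtype=object)
    for name, geom in zones.counties.items():
        inside = shapely.intersects_xy(geom, x, y)
        county[inside] = name
    n_orphan = int((county == "none").sum())
    if n_orphan:
        log.info("%d retained pixels fall in no county; excluded from county tables", n_orphan)

    cost_effective = (vpt_px <= vpt_onsite) & (slope_px < slope_cable) & (road_dist <= road_cutoff_m)
    return pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "x": x,
            "y": y,
            "tdbm_upper": upper.tdbm[rows, cols],
            "tdbm_lower": lower.tdbm[rows, cols],
            "vpt": vpt_px,
            "vpt_class": _vpt_class(vpt_px),
            "slope_percent": slope_px,
            "slope_class": _slope_class(slope_px),
            "road_distance_m": road_dist,
            "road_class": np.where(road_dist <= road_cutoff_m, "near", "far"),
            "hhz_tier1": tier1,
            "hhz_tier2": tier2,
            "county": county.astype(str),
            "cost_effective": cost_effective,
        }
    )


def _sums(df: pd.DataFrame) -> tuple[float, float]:
    return float(df["tdbm_lower"].sum()), float(df["tdbm_upper"].sum())


def summarize(table: pd.DataFrame, gross: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Roll the pixel table up into the standard report tables.

    Returns a dict with:

    * ``"criteria"`` — per cost criterion (on-site chipping, ground-based
      slope, road accessibility), biomass passing vs failing, per bound;
    * ``"hhz"`` — feasible and cost-effective biomass by High Hazard Zone
      tier, the tier-1-union-tier-2 total, and the no-HHZ remainder (tiers
      overlap, so tier rows can sum to more than the union row);
    * ``"county"`` — per county: gross, feasible and cost-effective
      biomass (thousand BDT) and the cost-effective share of gross (%,
      2 decimals), when ``gross`` (a per-pixel frame with columns
      ``county``, ``tdbm_upper``, ``tdbm_lower`` covering the unfiltered
      grid) is supplied.

    Percentages are computed from unrounded totals and rounded only for
    presentation.
    """
    crit_rows = []
    for label, passing in [
        ("onsite_chipping_vpt", table["vpt_class"] == "onsite_chippable"),
        ("ground_based_slope", table["slope_percent"] < SLOPE_CABLE),
        ("road_accessibility", table["road_class"] == "near"),
    ]:
        lo_ce, up_ce = _sums(table[passing])
        lo_nc, up_nc = _sums(table[~passing])
        crit_rows.append(
            {
                "criterion": label,
                "lower_not_cost_effective": lo_nc,
                "lower_cost_effective": lo_ce,
                "upper_not_cost_effective": up_nc,
                "upper_cost_effective": up_ce,
            }
        )
    criteria = pd.DataFrame(crit_rows)

    ce = table[table["cost_effective"]]
    hhz_rows = []
    for label, mask in [
        ("tier1", table["hhz_tier1"]),
        ("tier2", table["hhz_tier2"]),
        ("total_in_hhz", table["hhz_tier1"] | table["hhz_tier2"]),
        ("no_hhz", ~(table["hhz_tier1"] | table["hhz_tier2"])),
    ]:
        lo_f, up_f = _sums(table[mask])
        lo_c, up_c = _sums(ce[mask[ce.index]])
        hhz_rows.append(
            {
                "hhz": label,
                "lower_feasible": lo_f,
                "upper_feasible": up_f,
                "lower_cost_effective": lo_c,
                "upper_cost_effective": up_c,
            }
        )
    hhz = pd.DataFrame(hhz_rows)

    out = {"criteria": criteria, "hhz": hhz}
    if gross is not None:
        county_rows = []
        names = sorted(set(gross["county"]) | set(table["county"]))
        for name in names:
            if name == "none":
                continue
            g = gross[gross["county"] == name]
            f = table[table["county"] == name]
            c = f[f["cost_effective"]]
            g_lo, g_up = _sums(g)
            f_lo, f_up = _sums(f)
            c_lo, c_up = _sums(c)
            county_rows.append(
                {
                    "county": name,
                    "gross_upper_kbdt": g_up / 1e3,
                    "gross_lower_kbdt": g_lo / 1e3,
                    "feasible_upper_kbdt": f_up / 1e3,
                    "feasible_lower_kbdt": f_lo / 1e3,
                    "cost_effective_upper_kbdt": c_up / 1e3,
                    "cost_effective_lower_kbdt": c_lo / 1e3,
                    "ce_pct_of_gross_upper": round(100.0 * c_up / g_up, 2) if g_up > 0 else np.nan,
                    "ce_pct_of_gross_lower": round(100.0 * c_lo / g_lo, 2) if g_lo > 0 else np.nan,
                }
            )
        out["county"] = pd.DataFrame(county_rows)
    return out
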