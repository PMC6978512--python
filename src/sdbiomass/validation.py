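"""Polygon-level comparison against an independent biomass-loss raster.

The estimation pipeline is validated by summing, for each survey polygon,
(a) its own dead-biomass estimate (both bound variants, yearly layers
summed over the comparison window and capped at live biomass per pixel)
and (b) an independently produced biomass-loss raster over the same
pixels, excluding pixels where the reference predicts net biomass *gain*
(growth outstripping mortality).  Agreement is scored as RMSE of the
difference of natural-log-transformed sums — the log transform tames the
strong heteroscedasticity of biomass totals.  Note that log-scale RMSE is
base-dependent: natural logs are used throughout.

Polygons are excluded from the comparison when they are smaller than a
minimum area (default 2700 m^2, i.e. three 30-m pixels, below which
polygon/pixel alignment is unreliable), when they fail the minimum
harvest-feasibility screens (mean tree volume, dead-tree density, spatial
isolation), or when either side of the comparison is non-positive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .allocation import DeadBiomassGrid
from .geodata import GridAlignmentError, MortalityPolygon, StructureGrid, pixels_in_polygon

__all__ = ["MIN_POLYGON_AREA_M2", "polygon_comparison", "log_rmse"]

log = logging.getLogger(__name__)

MIN_POLYGON_AREA_M2 = 2700.0  # three 30-m pixels


def _capped_estimate(
    grid: DeadBiomassGrid,
    structure: StructureGrid,
    rows: np.ndarray,
    cols: np.ndarray,
    year_range: tuple[int, int],
) -> float:
    """Sum of per-pixel dead biomass over the window, live-biomass capped."""
    t0, t1 = year_range
    total = np.zeros(rows.size)
    for t, arr in grid.dbm_by_year.items():
        if t0 <= t <= t1:
            total += arr[rows, cols]
    cap = structure.bph[rows, cols] * structure.spec.pixel_area_ha
    return float(np.minimum(total, cap).sum())


def polygon_comparison(
    polys: list[MortalityPolygon],
    upper: DeadBiomassGrid,
    lower: DeadBiomassGrid,
    structure_upper: StructureGrid,
    structure_lower: StructureGrid,
    reference: np.ndarray,
    vpt: np.ndarray,
    year_range: tuple[int, int] = (2012, 2016),
    min_polygon_area_m2: float = MIN_POLYGON_AREA_M2,
    vpt_max: float = 11.32,
    min_dead_density: float = 2.5,
    clustered_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-polygon estimate vs reference sums with exclusion bookkeeping.

    ``clustered_mask``, when given, marks pixels that belong to a spatial
    cluster; a polygon none of whose dead-biomass pixels are clustered is
    excluded as spatially isolated.  Returns one row per polygon with
    columns ``included`` and ``exclusion_reason`` in
    {"", "too_small", "infeasible", "zero"}.
    """
    if reference.shape != upper.spec.shape:
        raise GridAlignmentError("reference raster not on the analysis grid")
    area_ha_px = upper.spec.pixel_area_ha
    records = []
    for poly in polys:
        if not (year_range[0] <= poly.year <= year_range[1]):
            continue
        rows, cols = pixels_in_polygon(poly.geometry, upper.spec)
        ref_px = reference[rows, cols] if rows.size else np.zeros(0)
        ref_sum = float(ref_px[ref_px > 0].sum())  # net-gain pixels contribute nothing
        est_up = _capped_estimate(upper, structure_upper, rows, cols, year_range)
        est_lo = _capped_estimate(lower, structure_lower, rows, cols, year_range)

        reason = ""
        if poly.geometry.area < min_polygon_area_m2:
            reason = "too_small"
        elif rows.size:
            tph = structure_upper.tph[rows, cols]
            forested = tph > 0
            mean_vpt = float(vpt[rows, cols][forested].mean()) if forested.any() else np.inf
            dead_density = float(upper.total_dt()[rows, cols].sum() / (rows.size * area_ha_px))
            isolated = False
            if clustered_mask is not None:
                sd_px = upper.tdbm[rows, cols] > 0
                isolated = not bool(clustered_mask[rows, cols][sd_px].any())
            if mean_vpt >= vpt_max or dead_density <= min_dead_density or isolated:
                reason = "infeasible"
        if not reason and (ref_sum <= 0 or est_up <= 0 or est_lo <= 0):
            reason = "zero"
        records.append(
            {
                "polygon_id": poly.polygon_id,
                "year": poly.year,
                "n_pixels": int(rows.size),
                "area_m2": float(poly.geometry.area),
                "pipeline_estimate_upper": est_up,
                "pipeline_estimate_lower": est_lo,
                "reference_loss": ref_sum,
                "included": reason == "",
                "exclusion_reason": reason,
            }
        )
    df = pd.DataFrame(
        records,
        columns=[
            "polygon_id",
            "year",
            "n_pixels",
            "area_m2",
            "pipeline_estimate_upper",
            "pipeline_estimate_lower",
            "reference_loss",
            "included",
            "exclusion_reason",
        ],
    )
    n_excluded = int((~df["included"]).sum()) if len(df) else 0
    log.info("validation: %d polygons compared, %d excluded", len(df), n_excluded)
    return df


def log_rmse(records: pd.DataFrame, which: str = "upper") -> float:
    """RMSE of ln(estimate) - ln(reference) over included polygon records.

    Self-comparison gives exactly 0; the statistic is invariant to a common
    multiplicative rescaling of both sides.  Raises if no included record
    or any included record is non-positive on either side.
    """
    if which not in ("upper", "lower"):
        raise ValueError("which must be 'upper' or 'lower'")
    inc = records[records["included"]]
    if len(inc) == 0:
        raise ValueError("no included records")
    est = inc[f"pipeline_estimate_{which}"].to_numpy(dtype=float)
    ref = inc["reference_loss"].to_numpy(dtype=float)
    if np.any(est <= 0) or np.any(ref <= 0):
        raise ValueError("included records must have positive estimate and reference")
    return float(np.sqrt(np.mean((np.log(est) - np.log(ref)) ** 2)))
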