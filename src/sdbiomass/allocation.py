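"""Dead-tree allocation and dead-biomass accounting.

Each aerial-survey polygon *p* in year *t* carries a dead-tree count
DT_p,t.  That count is distributed across the forested 30-m pixels *i*
inside the polygon in proportion to each pixel's pre-die-off live tree
density TPH_i, capped at the pixel's live tree stock:

    DT_i,t = min( DT_p,t * TPH_i / sum_{i in p} TPH_i ,  TPH_i * 0.09 )

(0.09 ha is the pixel area).  Dead biomass follows from the pixel's mean
live-tree biomass:

    DBM_i,t = DT_i,t * BPH_i / TPH_i

and the cumulative total over years is capped at the pixel's live biomass:

    TDBM_i = min( sum_t DBM_i,t ,  BPH_i * 0.09 )

Surplus truncated by the per-pixel cap is *not* redistributed to other
pixels; it is only logged.  Overlapping polygons are allocated
independently against the same pre-die-off structure; overlaps are
reconciled only by the cumulative cap.  Per-year layers are kept
uncorrected (the cumulative correction cannot be attributed to years).
The whole procedure is run twice, against structure layers restricted to
trees >= 25 cm DBH (upper-bound biomass) and >= 2.5 cm DBH (lower bound),
bracketing the aerial detection threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import (
    GridAlignmentError,
    GridSpec,
    MortalityPolygon,
    StructureGrid,
    pixels_in_polygon,
)

__all__ = [
    "DeadBiomassGrid",
    "allocate_polygon",
    "dead_biomass",
    "accumulate",
    "run_allocation",
]

log = logging.getLogger(__name__)


@dataclass
class DeadBiomassGrid:
    """Per-pixel dead trees and biomass for one detection-threshold variant."""

    spec: GridSpec
    variant: str
    dt_by_year: dict[int, np.ndarray]
    dbm_by_year: dict[int, np.ndarray]
    tdbm: np.ndarray
    diagnostics: pd.DataFrame  # one row per polygon: requested vs allocated
    correction_stats: dict = field(default_factory=dict)

    def total_dt(self) -> np.ndarray:
        """Cumulative dead trees per pixel across years (uncapped sum of yearly layers)."""
        if not self.dt_by_year:
            return np.zeros(self.spec.shape)
        return np.sum(list(self.dt_by_year.values()), axis=0)

    def copy(self) -> "DeadBiomassGrid":
        return DeadBiomassGrid(
            spec=self.spec,
            variant=self.variant,
            dt_by_year={t: a.copy() for t, a in self.dt_by_year.items()},
            dbm_by_year={t: a.copy() for t, a in self.dbm_by_year.items()},
            tdbm=self.tdbm.copy(),
            diagnostics=self.diagnostics.copy(),
            correction_stats=dict(self.correction_stats),
        )


def allocate_polygon(
    poly: MortalityPolygon, structure: StructureGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Distribute one polygon's dead-tree count over its forested pixels.

    Returns ``(rows, cols, dt, info)`` where ``dt`` are per-pixel dead-tree
    counts (fractional allowed) and ``info`` records requested vs allocated
    totals.  Pixels with TPH = 0 receive nothing; a polygon with no live
    trees at all allocates nothing and is logged.
    """
    area_ha = structure.spec.pixel_area_ha
    rows, cols = pixels_in_polygon(poly.geometry, structure.spec)
    tph = structure.tph[rows, cols]
    forested = tph > 0
    rows, cols, tph = rows[forested], cols[forested], tph[forested]
    info = {
        "polygon_id": poly.polygon_id,
        "year": poly.year,
        "requested": poly.dead_trees,
        "n_pixels": int(rows.size),
        "allocated": 0.0,
        "n_capped": 0,
    }
    if rows.size == 0 or tph.sum() == 0:
        if poly.dead_trees > 0:
            log.warning(
                "polygon %s (year %s): %.3f dead trees over zero live trees; nothing allocated",
                poly.polygon_id,
                poly.year,
                poly.dead_trees,
            )
        return rows, cols, np.zeros(0), info
    share = poly.dead_trees * tph / tph.sum()
    cap = tph * area_ha
    dt = np.minimum(share, cap)
    info["allocated"] = float(dt.sum())
    info["n_capped"] = int(np.sum(share > cap))
    return rows, cols, dt, info


def dead_biomass(dt: np.ndarray, structure: StructureGrid) -> np.ndarray:
    """Convert a per-pixel dead-tree raster to dead biomass (BDT/pixel).

    Multiplies by the pixel's mean live-tree biomass BPH/TPH; zero wherever
    TPH = 0 (guarded division).
    """
    if dt.shape != structure.spec.shape:
        raise GridAlignmentError("dead-tree raster not on the structure grid")
    mtb = np.divide(
        structure.bph, structure.tph, out=np.zeros(structure.spec.shape), where=structure.tph > 0
    )
    return dt * mtb


def accumulate(
    dbm_by_year: dict[int, np.ndarray], structure: StructureGrid
) -> tuple[np.ndarray, dict]:
    """Sum yearly dead biomass and cap at the pixel's live biomass.

    Returns the capped cumulative raster and correction statistics: the
    fraction of affected pixels that needed the cap and the biomass the cap
    removed (which equals sum_t DBM - TDBM exactly, by construction).
    """
    shape = structure.spec.shape
    for t, arr in dbm_by_year.items():
        if arr.shape != shape:
            raise GridAlignmentError(f"year {t} raster not on the structure grid")
    total = np.sum(list(dbm_by_year.values()), axis=0) if dbm_by_year else np.zeros(shape)
    live = structure.bph * structure.spec.pixel_area_ha
    tdbm = np.minimum(total, live)
    affected = total > 0
    corrected = affected & (total > live)
    stats = {
        "n_pixels_affected": int(affected.sum()),
        "n_pixels_corrected": int(corrected.sum()),
        "corrected_fraction": float(corrected.sum() / affected.sum()) if affected.any() else 0.0,
        "biomass_removed": float((total - tdbm).sum()),
        "biomass_removed_fraction": float((total - tdbm).sum() / total.sum())
        if total.sum() > 0
        else 0.0,
    }
    if stats["n_pixels_corrected"]:
        log.info(
            "cumulative cap: %.1f%% of affected pixels corrected, %.3f BDT removed (%.2f%% of sum)",
            100 * stats["corrected_fraction"],
            stats["biomass_removed"],
            100 * stats["biomass_removed_fraction"],
        )
    return tdbm, stats


def _allocate_variant(polys: list[MortalityPolygon], structure: StructureGrid) -> DeadBiomassGrid:
    shape = structure.spec.shape
    years = sorted({p.year for p in polys})
    dt_by_year = {t: np.zeros(shape) for t in years}
    diag_rows = []
    for poly in polys:
        rows, cols, dt, info = allocate_polygon(poly, structure)
        if rows.size:
            np.add.at(dt_by_year[poly.year], (rows, cols), dt)
        diag_rows.append(info)
    dbm_by_year = {t: dead_biomass(a, structure) for t, a in dt_by_year.items()}
    tdbm, stats = accumulate(dbm_by_year, structure)
    diagnostics = pd.DataFrame(
        diag_rows, columns=["polygon_id", "year", "requested", "n_pixels", "allocated", "n_capped"]
    )
    return DeadBiomassGrid(
        spec=structure.spec,
        variant=structure.variant,
        dt_by_year=dt_by_year,
        dbm_by_year=dbm_by_year,
        tdbm=tdbm,
        diagnostics=diagnostics,
        correction_stats=stats,
    )


def run_allocation(
    polys: list[MortalityPolygon],
    structure_upper: StructureGrid,
    structure_lower: StructureGrid,
) -> tuple[DeadBiomassGrid, DeadBiomassGrid]:
    """Run the allocation against both structure variants.

    The same survey counts drive both runs; only the structure layers
    differ.  Returns ``(upper, lower)`` dead-biomass grids, where *upper*
    uses the >= 25 cm DBH layers and *lower* the >= 2.5 cm layers.
    """
    if structure_upper.spec != structure_lower.spec:
        raise GridAlignmentError("structure variants are on different grids")
    upper = _allocate_variant(polys, structure_upper)
    lower = _allocate_variant(polys, structure_lower)
    for g in (upper, lower):
        log.info(
            "%s: cumulative dead biomass %.1f BDT over %d pixels",
            g.variant,
            g.tdbm.sum(),
            int((g.tdbm > 0).sum()),
        )
    return upper, lower
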