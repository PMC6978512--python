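"""End-to-end orchestration: allocate -> filter -> classify -> energy -> validate.

`run_pipeline` executes the full analysis on an in-memory input bundle
and returns every intermediate and final artifact; `write_results` lays
the tables out as CSV.  All stages are deterministic given the inputs, so
identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification, feasibility
from .allocation import DeadBiomassGrid, run_allocation
from .classification import classify_pixels, slope_percent, summarize
from .energy import (
    CarbonParams,
    EnergyParams,
    annual_generation_twh,
    bdt_to_mwh,
    bdt_to_tg_carbon,
    facility_radius_feedstock,
    years_of_supply,
)
from .feasibility import (
    DEFAULT_EPS_SWEEP,
    DEFAULT_MIN_PTS,
    dbscan,
    filter_isolated,
    filter_vpt_and_density,
    filter_zones,
    mean_tree_volume,
    select_eps,
    tradeoff_curve,
    vpt_density_drop_mask,
)
from .synthetic import Bundle
from .validation import log_rmse, polygon_comparison

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline", "write_results"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """All thresholds of the analysis; defaults are the published values."""

    eps_m: float | None = None  # None -> select from the trade-off curve
    eps_sweep: tuple[float, ...] = DEFAULT_EPS_SWEEP
    min_pts: int = DEFAULT_MIN_PTS
    vpt_max: float = feasibility.VPT_MAX
    min_dead_density: float = feasibility.MIN_DEAD_DENSITY
    vpt_onsite: float = classification.VPT_ONSITE
    slope_ground: float = classification.SLOPE_GROUND
    slope_cable: float = classification.SLOPE_CABLE
    road_cutoff_m: float = classification.ROAD_CUTOFF_M
    energy: EnergyParams = field(default_factory=EnergyParams)
    carbon: CarbonParams = field(default_factory=CarbonParams)
    validation_year_range: tuple[int, int] = (2012, 2016)
    facility_site: tuple[float, float] | None = None
    facility_radii_m: tuple[float, ...] = (30_000.0, 50_000.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["energy"] = dataclasses.asdict(self.energy)
        d["carbon"] = dataclasses.asdict(self.carbon)
        return d


@dataclass
class PipelineResult:
    params: PipelineParams
    gross_upper: DeadBiomassGrid
    gross_lower: DeadBiomassGrid
    feasible_upper: DeadBiomassGrid
    feasible_lower: DeadBiomassGrid
    yearly_totals: pd.DataFrame  # uncorrected yearly dead biomass per variant
    tradeoff: pd.DataFrame | None
    eps_selected: float
    reduction_ledger: pd.DataFrame  # sequential-filter cascade
    pixel_table: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    energy_table: pd.DataFrame
    facility_table: pd.DataFrame | None
    validation_records: pd.DataFrame | None
    validation_rmse: dict[str, float] | None
    clustered_mask: np.ndarray

    def audit(self) -> None:
        """Internal consistency: every reported total re-derives from the pixel table."""
        t = self.pixel_table
        assert np.isclose(t["tdbm_upper"].sum(), self.feasible_upper.tdbm.sum())
        assert np.isclose(t["tdbm_lower"].sum(), self.feasible_lower.tdbm.sum())
        crit = self.summaries["criteria"]
        for _, row in crit.iterrows():
            total = row["upper_not_cost_effective"] + row["upper_cost_effective"]
            assert np.isclose(total, t["tdbm_upper"].sum())


def _yearly_totals(upper: DeadBiomassGrid, lower: DeadBiomassGrid) -> pd.DataFrame:
    years = sorted(upper.dbm_by_year)
    return pd.DataFrame(
        {
            "year": years,
            "upper_bdt": [float(upper.dbm_by_year[t].sum()) for t in years],
            "lower_bdt": [float(lower.dbm_by_year[t].sum()) for t in years],
        }
    )


def run_pipeline(bundle: Bundle, params: PipelineParams | None = None) -> PipelineResult:
    """Run the full analysis on a bundle.  Deterministic given its inputs."""
    if params is None:
        params = PipelineParams()
    spec = bundle.config.spec

    # --- allocation (both bound variants) ---------------------------------
    gross_upper, gross_lower = run_allocation(
        bundle.polygons, bundle.structure_upper, bundle.structure_lower
    )
    yearly = _yearly_totals(gross_upper, gross_lower)

    # --- spatial-isolation filter -----------------------------------------
    # Clustering runs on the upper-bound grid; the resulting noise mask is
    # applied to both variants so both bounds share one spatial footprint.
    rows, cols = np.nonzero(gross_upper.tdbm > 0)
    x, y = spec.center_of(rows, cols)
    curve = None
    if params.eps_m is None:
        curve = tradeoff_curve(gross_upper, params.eps_sweep, params.min_pts)
        eps = select_eps(curve)
    else:
        eps = params.eps_m
    assign = dbscan(rows, cols, x, y, eps=eps, min_pts=params.min_pts)
    iso_upper, rem_iso_up = filter_isolated(gross_upper, assign)
    iso_lower, rem_iso_lo = filter_isolated(gross_lower, assign)
    clustered_mask = np.zeros(spec.shape, dtype=bool)
    keep = ~assign.noise_mask()
    clustered_mask[assign.rows[keep], assign.cols[keep]] = True

    # --- wilderness / National Park ---------------------------------------
    wild_upper, rem_w_up = filter_zones(iso_upper, bundle.zones)
    wild_lower, rem_w_lo = filter_zones(iso_lower, bundle.zones)

    # --- tree size and dead-tree density ----------------------------------
    # VPT from the detection-matched variant, falling back to the all-tree
    # variant where the large-tree layer is empty.
    vpt_up = mean_tree_volume(bundle.structure_upper)
    vpt_lo = mean_tree_volume(bundle.structure_lower)
    vpt = np.where(bundle.structure_upper.tph > 0, vpt_up, vpt_lo)
    drop = vpt_density_drop_mask(gross_upper, vpt, params.vpt_max, params.min_dead_density)
    feas_upper, rem_v_up = filter_vpt_and_density(wild_upper, vpt, drop_mask=drop)
    feas_lower, rem_v_lo = filter_vpt_and_density(wild_lower, vpt, drop_mask=drop)

    ledger = pd.DataFrame(
        {
            "filter": ["gross", "spatial_isolation", "wilderness_np", "vpt_or_density"],
            "lower_reduction_bdt": [0.0, rem_iso_lo, rem_w_lo, rem_v_lo],
            "lower_total_bdt": [
                float(gross_lower.tdbm.sum()),
                float(iso_lower.tdbm.sum()),
                float(wild_lower.tdbm.sum()),
                float(feas_lower.tdbm.sum()),
            ],
            "upper_reduction_bdt": [0.0, rem_iso_up, rem_w_up, rem_v_up],
            "upper_total_bdt": [
                float(gross_upper.tdbm.sum()),
                float(iso_upper.tdbm.sum()),
                float(wild_upper.tdbm.sum()),
                float(feas_upper.tdbm.sum()),
            ],
        }
    )

    # --- classification -----------------------------------------------------
    slope = slope_percent(bundle.dem, spec.pixel_size)
    table = classify_pixels(
        feas_upper,
        feas_lower,
        vpt,
        slope,
        bundle.roads,
        bundle.zones,
        vpt_onsite=params.vpt_onsite,
        slope_cable=params.slope_cable,
        road_cutoff_m=params.road_cutoff_m,
    )
    g_rows, g_cols = np.nonzero((gross_upper.tdbm > 0) | (gross_lower.tdbm > 0))
    gx, gy = spec.center_of(g_rows, g_cols)
    county = np.full(g_rows.size, "none", dtype=object)
    import shapely

    for name, geom in bundle.zones.counties.items():
        inside = shapely.intersects_xy(geom, gx, gy)
        county[inside] = name
    gross_table = pd.DataFrame(
        {
            "county": county.astype(str),
            "tdbm_upper": gross_upper.tdbm[g_rows, g_cols],
            "tdbm_lower": gross_lower.tdbm[g_rows, g_cols],
        }
    )
    summaries = summarize(table, gross=gross_table)

    # --- energy and carbon ---------------------------------------------------
    feas_up_total = float(feas_upper.tdbm.sum())
    feas_lo_total = float(feas_lower.tdbm.sum())
    ce = table[table["cost_effective"]]
    ce_up_total = float(ce["tdbm_upper"].sum())
    ce_lo_total = float(ce["tdbm_lower"].sum())
    annual_twh = annual_generation_twh(params.energy)
    energy_rows = []
    for label, lo_total, up_total in [
        ("feasible", feas_lo_total, feas_up_total),
        ("cost_effective", ce_lo_total, ce_up_total),
    ]:
        energy_rows.append(
            {
                "subset": label,
                "lower_bdt": lo_total,
                "upper_bdt": up_total,
                "lower_boiler_twh": bdt_to_mwh(lo_total, params.energy, "boiler") / 1e6,
                "upper_boiler_twh": bdt_to_mwh(up_total, params.energy, "boiler") / 1e6,
                "lower_gasifier_twh": bdt_to_mwh(lo_total, params.energy, "gasifier") / 1e6,
                "upper_gasifier_twh": bdt_to_mwh(up_total, params.energy, "gasifier") / 1e6,
                "lower_supply_years": years_of_supply(lo_total, annual_twh, params.energy),
                "upper_supply_years": years_of_supply(up_total, annual_twh, params.energy),
                "lower_tg_c": bdt_to_tg_carbon(lo_total, params.carbon),
                "upper_tg_c": bdt_to_tg_carbon(up_total, params.carbon),
            }
        )
    energy_table = pd.DataFrame(energy_rows)

    facility = None
    if params.facility_site is not None:
        facility = facility_radius_feedstock(
            table, params.facility_site[0], params.facility_site[1], list(params.facility_radii_m)
        )

    # --- validation -----------------------------------------------------------
    records = None
    rmse = None
    if bundle.reference_loss is not None:
        records = polygon_comparison(
            bundle.polygons,
            gross_upper,
            gross_lower,
            bundle.structure_upper,
            bundle.structure_lower,
            bundle.reference_loss,
            vpt,
            year_range=params.validation_year_range,
            vpt_max=params.vpt_max,
            min_dead_density=params.min_dead_density,
            clustered_mask=clustered_mask,
        )
        rmse = {}
        for which in ("upper", "lower"):
            try:
                rmse[which] = log_rmse(records, which)
            except ValueError:
                rmse[which] = float("nan")

    result = PipelineResult(
        params=params,
        gross_upper=gross_upper,
        gross_lower=gross_lower,
        feasible_upper=feas_upper,
        feasible_lower=feas_lower,
        yearly_totals=yearly,
        tradeoff=curve,
        eps_selected=float(eps),
        reduction_ledger=ledger,
        pixel_table=table,
        summaries=summaries,
        energy_table=energy_table,
        facility_table=facility,
        validation_records=records,
        validation_rmse=rmse,
        clustered_mask=clustered_mask,
    )
    result.audit()
    return result


def write_results(result: PipelineResult, directory: str | Path) -> None:
    """Write every table of a pipeline run as CSV under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    result.yearly_totals.to_csv(directory / "yearly_totals.csv", index=False)
    result.reduction_ledger.to_csv(directory / "reduction_ledger.csv", index=False)
    if result.tradeoff is not None:
        result.tradeoff.to_csv(directory / "tradeoff_curve.csv", index=False)
    result.pixel_table.to_csv(directory / "pixel_table.csv", index=False)
    for name, df in result.summaries.items():
        df.to_csv(directory / f"summary_{name}.csv", index=False)
    result.energy_table.to_csv(directory / "energy.csv", index=False)
    if result.facility_table is not None:
        result.facility_table.to_csv(directory / "facility_radius.csv", index=False)
    if result.validation_records is not None:
        result.validation_records.to_csv(directory / "validation_records.csv", index=False)
        pd.DataFrame([result.validation_rmse]).to_csv(directory / "validation_rmse.csv", index=False)
    (directory / "eps_selected.txt").write_text(f"{result.eps_selected}\n")
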