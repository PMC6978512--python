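"""Synthetic landscape bundles with retained ground truth.

Real analyses of post-die-off standing-dead (SD) biomass fuse three data
streams that are too large to ship: wall-to-wall 30-m forest-structure
rasters (live trees, biomass and stem volume per hectare, imputed in two
tree-size variants), yearly aerial-survey mortality polygons carrying
dead-tree counts, and ancillary terrain/road/administrative layers.  This
module emulates all of them on a small grid, keeping the per-pixel truth
that generated the survey counts so every downstream stage can be tested
for exact recovery.

The structure fields are spatially autocorrelated (Gaussian-smoothed white
noise); mortality polygons are blob-shaped (buffered random walks) with
counts either exactly proportional to pixel tree density (so proportional
allocation recovers the truth to machine precision) or deliberately
size-biased (so the estimator's error can be exercised); the DEM can be
flat, an inclined plane of known slope, or a random smooth surface.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from shapely.geometry import LineString, Polygon, box

from .geodata import (
    GridSpec,
    MortalityPolygon,
    RoadNetwork,
    StructureGrid,
    ZoneSet,
    pixels_in_polygon,
    write_grid,
    write_mortality,
    write_roads,
    write_structure,
    write_zones,
)

__all__ = [
    "LandscapeConfig",
    "GroundTruth",
    "Bundle",
    "generate_structure",
    "generate_mortality",
    "generate_reference_loss",
    "generate_dem",
    "generate_roads",
    "generate_zones",
    "generate_bundle",
    "write_bundle",
    "read_bundle",
]

PIXEL_AREA_HA = 0.09  # 30 m pixel


@dataclass(frozen=True)
class LandscapeConfig:
    """Knobs of the synthetic landscape.

    Defaults describe a 4.5 km x 4.5 km mountain-forest scene surveyed for
    six consecutive years, with per-polygon mortality fractions typical of a
    severe drought/beetle die-off (well above background, below total
    stand loss).
    """

    seed: int = 0
    spec: GridSpec = field(
        default_factory=lambda: GridSpec(
            origin_x=500_000.0, origin_y=4_200_000.0, n_rows=150, n_cols=150
        )
    )
    forest_fraction: float = 0.7
    tph_mean: float = 300.0  # live trees/ha, all-tree (>=2.5 cm DBH) variant
    tph_spatial_scale: float = 6.0  # smoothing sigma, pixels
    large_tree_fraction_range: tuple[float, float] = (0.25, 0.55)
    mean_tree_biomass_range: tuple[float, float] = (0.08, 0.45)  # BDT/tree, all-tree
    mean_tree_volume_range: tuple[float, float] = (0.2, 4.0)  # m3/tree, all-tree
    n_polygons_per_year: int = 8
    years: tuple[int, ...] = (2012, 2013, 2014, 2015, 2016, 2017)
    mortality_fraction_range: tuple[float, float] = (0.02, 0.35)
    mortality_mode: str = "proportional"  # or "size_biased"
    polygon_placement: str = "random"  # "tiled" -> non-overlapping polygons
    polygon_radius_px: tuple[float, float] = (1.5, 4.0)
    slope_mode: str = "random"  # flat | inclined | random
    rise_percent: float = 30.0  # inclined-plane slope
    relief_rms_slope_percent: float = 25.0  # random-DEM target RMS slope
    n_roads: int = 4
    zone_fractions: dict = field(
        default_factory=lambda: {
            "wilderness_np": 0.15,
            "hhz_tier1": 0.10,
            "hhz_tier2": 0.35,
        }
    )
    n_counties: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.forest_fraction <= 1.0:
            raise ValueError("forest_fraction must be in [0, 1]")
        lo, hi = self.mortality_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("mortality_fraction_range must be within [0, 1]")
        if self.mortality_mode not in ("proportional", "size_biased"):
            raise ValueError(f"unknown mortality_mode {self.mortality_mode!r}")
        if self.polygon_placement not in ("random", "tiled"):
            raise ValueError(f"unknown polygon_placement {self.polygon_placement!r}")
        if self.slope_mode not in ("flat", "inclined", "random"):
            raise ValueError(f"unknown slope_mode {self.slope_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spec"] = self.spec.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeConfig":
        d = dict(d)
        d["spec"] = GridSpec.from_dict(d["spec"])
        for key in ("years",):
            if key in d:
                d[key] = tuple(d[key])
        for key in (
            "large_tree_fraction_range",
            "mean_tree_biomass_range",
            "mean_tree_volume_range",
            "mortality_fraction_range",
            "polygon_radius_px",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PolygonTruth:
    """Per-polygon record of the pixels and true dead counts it was built from."""

    polygon_id: str
    year: int
    rows: np.ndarray
    cols: np.ndarray
    dt: np.ndarray  # true dead trees contributed by this polygon, per pixel
    dbm: np.ndarray  # true dead biomass (BDT) contributed, per pixel


@dataclass
class GroundTruth:
    """Pixel-level truth behind the survey polygons.

    Truth is expressed against one structure variant (``variant``) whose
    tree densities were used to place mortality; the cumulative dead
    biomass ``tdbm`` is capped at that variant's live biomass per pixel,
    mirroring the estimator's own cumulative cap.
    """

    variant: str
    spec: GridSpec
    dt_by_year: dict[int, np.ndarray]
    dbm_by_year: dict[int, np.ndarray]
    tdbm: np.ndarray
    per_polygon: list[PolygonTruth]

    def polygon_totals(self) -> dict[str, float]:
        return {pt.polygon_id: float(pt.dt.sum()) for pt in self.per_polygon}


@dataclass
class Bundle:
    """A complete synthetic input set plus its ground truth."""

    config: LandscapeConfig
    structure_upper: StructureGrid  # dbh_ge_25cm
    structure_lower: StructureGrid  # dbh_ge_2p5cm
    polygons: list[MortalityPolygon]
    truth: GroundTruth
    dem: np.ndarray
    roads: RoadNetwork
    zones: ZoneSet
    reference_loss: np.ndarray | None = None


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent substreams so components regenerate independently."""
    names = ["structure", "mortality", "dem", "roads", "zones", "reference"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-ish smoothed white noise, rescaled to zero mean / unit sd."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _range_field(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float, lo: float, hi: float
) -> np.ndarray:
    """Smooth field mapped through a logistic into (lo, hi)."""
    z = _smooth_field(rng, shape, sigma)
    u = 1.0 / (1.0 + np.exp(-z))
    return lo + (hi - lo) * u


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

def generate_structure(config: LandscapeConfig) -> tuple[StructureGrid, StructureGrid]:
    """Generate both detection-threshold variants of the structure grid.

    Construction guarantees the subset relations a size-thresholded
    inventory obeys: pixelwise TPH(>=25cm) <= TPH(>=2.5cm), BPH and VPH
    likewise, while the *mean tree* biomass and volume of the large-tree
    subset are >= those of the all-tree population.
    """
    rng = _streams(config.seed)["structure"]
    shape = config.spec.shape
    sig = config.tph_spatial_scale

    if config.forest_fraction == 0.0:
        zero = np.zeros(shape)
        mask = np.zeros(shape, dtype=bool)
        up = StructureGrid(config.spec, "dbh_ge_25cm", zero.copy(), zero.copy(), zero.copy(), mask.copy())
        lo = StructureGrid(config.spec, "dbh_ge_2p5cm", zero.copy(), zero.copy(), zero.copy(), mask)
        return up, lo

    suit = _smooth_field(rng, shape, sig)
    thresh = np.quantile(suit, 1.0 - config.forest_fraction)
    forest = suit >= thresh

    density = _range_field(rng, shape, sig, 0.3, 1.7) * config.tph_mean
    tph_low = np.where(forest, density, 0.0)

    f_lo, f_hi = config.large_tree_fraction_range
    frac_large = _range_field(rng, shape, sig, f_lo, f_hi)
    tph_up = tph_low * frac_large

    b_lo, b_hi = config.mean_tree_biomass_range
    mtb_low = _range_field(rng, shape, sig, b_lo, b_hi)
    v_lo, v_hi = config.mean_tree_volume_range
    mtv_low = _range_field(rng, shape, sig, v_lo, v_hi)

    # Large-tree subset has heavier/bigger mean trees; boost g in (0,1) keeps
    # subset totals below population totals: mtb_up = mtb_low*(1+(1/f-1)*g)
    # implies bph_up = f*(1+(1/f-1)*g)*bph_low <= bph_low.
    g = _range_field(rng, shape, sig, 0.3, 0.9)
    boost = 1.0 + (1.0 / frac_large - 1.0) * g
    mtb_up = mtb_low * boost
    mtv_up = mtv_low * boost

    def grid(variant: str, tph: np.ndarray, mtb: np.ndarray, mtv: np.ndarray) -> StructureGrid:
        tph = np.where(forest, tph, 0.0)
        return StructureGrid(
            spec=config.spec,
            variant=variant,
            tph=tph,
            bph=tph * mtb,
            vph=tph * mtv,
            forest_mask=forest.copy(),
        )

    return (
        grid("dbh_ge_25cm", tph_up, mtb_up, mtv_up),
        grid("dbh_ge_2p5cm", tph_low, mtb_low, mtv_low),
    )


# ---------------------------------------------------------------------------
# Mortality polygons
# ---------------------------------------------------------------------------

def _blob(
    rng: np.random.Generator,
    spec: GridSpec,
    radius_px: float,
    n_steps: int = 10,
    bounds: tuple[float, float, float, float] | None = None,
) -> Polygon:
    """Buffered random walk: always a valid single-part polygon.

    When ``bounds`` is given the walk is confined so the buffered blob
    stays inside them (used for non-overlapping tiled placement).
    """
    px = spec.pixel_size
    if bounds is None:
        minx, miny, maxx, maxy = spec.bounds
        minx, miny = minx + 5 * px, miny + 5 * px
        maxx, maxy = maxx - 5 * px, maxy - 5 * px
    else:
        minx, miny, maxx, maxy = bounds
        pad = radius_px * px
        minx, miny, maxx, maxy = minx + pad, miny + pad, maxx - pad, maxy - pad
        if maxx <= minx or maxy <= miny:
            raise ValueError("tile too small for the requested blob radius")
    x = rng.uniform(minx, maxx)
    y = rng.uniform(miny, maxy)
    heading = rng.uniform(0, 2 * np.pi)
    pts = [(x, y)]
    for _ in range(n_steps):
        heading += rng.normal(0, 0.9)
        step = rng.uniform(1.0, 2.5) * px
        x = np.clip(x + step * np.cos(heading), minx, maxx)
        y = np.clip(y + step * np.sin(heading), miny, maxy)
        pts.append((x, y))
    return LineString(pts).buffer(radius_px * px)


def generate_mortality(
    config: LandscapeConfig, structure: StructureGrid
) -> tuple[list[MortalityPolygon], GroundTruth]:
    """Blob-shaped survey polygons with dead-tree counts and pixel truth.

    ``proportional`` mode draws a polygon mortality fraction and kills
    exactly that fraction of each forested member pixel's trees, so the
    polygon count distributed proportionally to pixel tree density equals
    the truth (no per-pixel cap ever binds within a polygon-year).
    ``size_biased`` mode skews deaths toward pixels with heavier mean
    trees, so a proportional allocator misallocates — by design.
    """
    rng = _streams(config.seed)["mortality"]
    spec = config.spec
    area_ha = spec.pixel_area_ha
    mtb = np.divide(structure.bph, structure.tph, out=np.zeros(spec.shape), where=structure.tph > 0)

    polys: list[MortalityPolygon] = []
    per_polygon: list[PolygonTruth] = []
    dt_by_year = {t: np.zeros(spec.shape) for t in config.years}
    dbm_by_year = {t: np.zeros(spec.shape) for t in config.years}

    tiles: list[tuple[float, float, float, float]] = []
    if config.polygon_placement == "tiled":
        r_max = config.polygon_radius_px[1]
        tile_px = max(int(np.ceil(4 * r_max)), 8)
        n_tx = spec.n_cols // tile_px
        n_ty = spec.n_rows // tile_px
        total = config.n_polygons_per_year * len(config.years)
        if n_tx * n_ty < total:
            raise ValueError(
                f"grid supports only {n_tx * n_ty} non-overlapping tiles; "
                f"{total} polygons requested"
            )
        minx, _, _, maxy = spec.bounds
        side = tile_px * spec.pixel_size
        for k in rng.permutation(n_tx * n_ty):
            tx, ty = int(k % n_tx), int(k // n_tx)
            tiles.append(
                (minx + tx * side, maxy - (ty + 1) * side, minx + (tx + 1) * side, maxy - ty * side)
            )
    tile_idx = 0

    for year in config.years:
        made = 0
        attempts = 0
        while made < config.n_polygons_per_year and attempts < config.n_polygons_per_year * 20:
            attempts += 1
            radius = rng.uniform(*config.polygon_radius_px)
            if config.polygon_placement == "tiled":
                if tile_idx >= len(tiles):
                    break
                geom = _blob(rng, spec, radius, bounds=tiles[tile_idx])
                tile_idx += 1
            else:
                geom = _blob(rng, spec, radius)
            rows, cols = pixels_in_polygon(geom, spec)
            tph = structure.tph[rows, cols]
            fmask = tph > 0
            if fmask.sum() < 3:
                continue
            rows, cols, tph = rows[fmask], cols[fmask], tph[fmask]
            frac = rng.uniform(*config.mortality_fraction_range)
            live_trees = tph * area_ha
            if config.mortality_mode == "proportional":
                dt_p = frac * live_trees.sum()
                dt = dt_p * tph / tph.sum()
            else:  # size_biased: deaths concentrate in big-tree pixels
                w = tph * mtb[rows, cols] ** 1.5
                if w.sum() == 0:
                    continue
                dt_p = frac * live_trees.sum()
                dt = np.minimum(dt_p * w / w.sum(), live_trees)
            pid = f"p{year}_{made:03d}"
            dbm = dt * mtb[rows, cols]
            polys.append(
                MortalityPolygon(
                    polygon_id=pid, year=year, geometry=geom, dead_trees=float(dt.sum())
                )
            )
            per_polygon.append(PolygonTruth(pid, year, rows, cols, dt, dbm))
            dt_by_year[year][rows, cols] += dt
            dbm_by_year[year][rows, cols] += dbm
            made += 1

    total_dbm = sum(dbm_by_year.values()) if config.years else np.zeros(spec.shape)
    tdbm = np.minimum(total_dbm, structure.bph * area_ha)
    truth = GroundTruth(
        variant=structure.variant,
        spec=spec,
        dt_by_year=dt_by_year,
        dbm_by_year=dbm_by_year,
        tdbm=tdbm,
        per_polygon=per_polygon,
    )
    return polys, truth


# ---------------------------------------------------------------------------
# Reference biomass-loss raster (independent-map emulation)
# ---------------------------------------------------------------------------

def generate_reference_loss(
    truth: GroundTruth,
    noise_sd_log: float,
    seed: int,
    gain_fraction: float = 0.0,
    gain_magnitude: float = 5.0,
) -> np.ndarray:
    """Independent biomass-loss raster: truth times lognormal noise.

    Noise is drawn once per survey polygon and applied to that polygon's
    contribution, emulating how an independent change map errs coherently
    across a disturbance patch; with little polygon overlap, polygon-level
    log-RMSE against the truth converges to ``noise_sd_log``.
    ``gain_fraction`` of randomly chosen pixels is overwritten with a
    negative value (net growth), exercising the validation exclusion rule.
    """
    if noise_sd_log < 0:
        raise ValueError("noise_sd_log must be >= 0")
    rng = np.random.default_rng(seed)
    ref = np.zeros(truth.spec.shape)
    for pt in truth.per_polygon:
        factor = float(np.exp(rng.normal(0.0, noise_sd_log))) if noise_sd_log > 0 else 1.0
        ref[pt.rows, pt.cols] += pt.dbm * factor
    if gain_fraction > 0:
        gain = rng.random(ref.shape) < gain_fraction
        ref[gain] = -rng.uniform(0.0, gain_magnitude, size=int(gain.sum()))
    return ref


# ---------------------------------------------------------------------------
# DEM, roads, zones
# ---------------------------------------------------------------------------

def generate_dem(config: LandscapeConfig) -> np.ndarray:
    """Elevation raster: flat, eastward inclined plane, or random smooth surface."""
    rng = _streams(config.seed)["dem"]
    spec = config.spec
    if config.slope_mode == "flat":
        return np.zeros(spec.shape)
    if config.slope_mode == "inclined":
        x = (np.arange(spec.n_cols) + 0.5) * spec.pixel_size
        return np.tile(x * config.rise_percent / 100.0, (spec.n_rows, 1))
    z = _smooth_field(rng, spec.shape, config.tph_spatial_scale * 1.5)
    gy, gx = np.gradient(z, spec.pixel_size)
    rms = np.sqrt(np.mean(gx**2 + gy**2))
    if rms == 0:
        return np.zeros(spec.shape)
    return z * (config.relief_rms_slope_percent / 100.0) / rms


def generate_roads(config: LandscapeConfig) -> RoadNetwork:
    """Simple wavy polylines crossing the extent, alternating E-W / N-S."""
    rng = _streams(config.seed)["roads"]
    spec = config.spec
    minx, miny, maxx, maxy = spec.bounds
    lines = []
    for k in range(config.n_roads):
        n_pts = 12
        if k % 2 == 0:  # roughly east-west
            xs = np.linspace(minx, maxx, n_pts)
            y0 = rng.uniform(miny, maxy)
            ys = y0 + np.cumsum(rng.normal(0, spec.pixel_size * 2, n_pts))
            ys = np.clip(ys, miny, maxy)
        else:  # roughly north-south
            ys = np.linspace(miny, maxy, n_pts)
            x0 = rng.uniform(minx, maxx)
            xs = x0 + np.cumsum(rng.normal(0, spec.pixel_size * 2, n_pts))
            xs = np.clip(xs, minx, maxx)
        lines.append(LineString(np.column_stack([xs, ys])))
    return RoadNetwork(lines=lines)


def _blob_cover(
    rng: np.random.Generator, spec: GridSpec, target_fraction: float
) -> list[Polygon]:
    """Blobs accumulated until they cover roughly ``target_fraction`` of the extent."""
    if target_fraction <= 0:
        return []
    extent = box(*spec.bounds)
    blobs: list[Polygon] = []
    covered = 0.0
    while covered < target_fraction * extent.area and len(blobs) < 50:
        radius = rng.uniform(6.0, 14.0)
        b = _blob(rng, spec, radius, n_steps=8).intersection(extent)
        if b.is_empty:
            continue
        blobs.append(b)
        from shapely import union_all

        covered = union_all(blobs).area
    return blobs


def generate_zones(config: LandscapeConfig) -> ZoneSet:
    """Wilderness/National-Park blobs, (possibly overlapping) HHZ tier blobs,
    and a rectangular partition of the extent into named counties."""
    rng = _streams(config.seed)["zones"]
    spec = config.spec
    zf = config.zone_fractions
    zones = ZoneSet(
        wilderness_np=_blob_cover(rng, spec, zf.get("wilderness_np", 0.0)),
        hhz_tier1=_blob_cover(rng, spec, zf.get("hhz_tier1", 0.0)),
        hhz_tier2=_blob_cover(rng, spec, zf.get("hhz_tier2", 0.0)),
    )
    minx, miny, maxx, maxy = spec.bounds
    n = max(config.n_counties, 1)
    n_x = int(np.ceil(np.sqrt(n)))
    n_y = int(np.ceil(n / n_x))
    xs = np.linspace(minx, maxx, n_x + 1)
    ys = np.linspace(miny, maxy, n_y + 1)
    idx = 0
    for i in range(n_y):
        for j in range(n_x):
            if idx >= n:
                break
            zones.counties[f"County_{idx + 1}"] = box(xs[j], ys[i], xs[j + 1], ys[i + 1])
            idx += 1
    return zones


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def generate_bundle(
    config: LandscapeConfig,
    reference_noise_sd_log: float | None = None,
    reference_gain_fraction: float = 0.0,
) -> Bundle:
    """Generate the full input set.  Deterministic given ``config.seed``."""
    upper, lower = generate_structure(config)
    # Mortality truth is placed against the detection-matched (>=25 cm) variant.
    polys, truth = generate_mortality(config, upper)
    bundle = Bundle(
        config=config,
        structure_upper=upper,
        structure_lower=lower,
        polygons=polys,
        truth=truth,
        dem=generate_dem(config),
        roads=generate_roads(config),
        zones=generate_zones(config),
    )
    if reference_noise_sd_log is not None:
        ref_seed = int(_streams(config.seed)["reference"].integers(2**31))
        bundle.reference_loss = generate_reference_loss(
            truth, reference_noise_sd_log, ref_seed, gain_fraction=reference_gain_fraction
        )
    return bundle


def write_bundle(bundle: Bundle, directory: str | Path) -> None:
    """Write the bundle to disk: GeoTIFFs, GeoJSONs, ground-truth CSV, config YAML."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = bundle.config.spec
    crs = spec.crs_id
    write_structure(directory, bundle.structure_upper)
    write_structure(directory, bundle.structure_lower)
    write_mortality(directory / "mortality.geojson", bundle.polygons, crs)
    write_grid(directory / "dem.tif", bundle.dem.astype(np.float64), spec)
    write_roads(directory / "roads.geojson", bundle.roads, crs)
    write_zones(directory / "zones.geojson", bundle.zones, crs)
    if bundle.reference_loss is not None:
        write_grid(directory / "reference_loss.tif", bundle.reference_loss.astype(np.float64), spec)
    rows = []
    for pt in bundle.truth.per_polygon:
        for r, c, dt, dbm in zip(pt.rows, pt.cols, pt.dt, pt.dbm):
            rows.append(
                {
                    "polygon_id": pt.polygon_id,
                    "year": pt.year,
                    "row": int(r),
                    "col": int(c),
                    "dt_true": dt,
                    "dbm_true": dbm,
                }
            )
    pd.DataFrame(
        rows, columns=["polygon_id", "year", "row", "col", "dt_true", "dbm_true"]
    ).to_csv(directory / "ground_truth.csv", index=False)
    (directory / "config.yaml").write_text(yaml.safe_dump(bundle.config.to_dict()))


def read_bundle(directory: str | Path) -> Bundle:
    """Read a bundle written by :func:`write_bundle`."""
    import pandas as pd

    from .geodata import read_grid, read_mortality, read_roads, read_structure, read_zones

    directory = Path(directory)
    config = LandscapeConfig.from_dict(yaml.safe_load((directory / "config.yaml").read_text()))
    spec = config.spec
    upper = read_structure(directory, "dbh_ge_25cm", spec)
    lower = read_structure(directory, "dbh_ge_2p5cm", spec)
    polys = read_mortality(directory / "mortality.geojson")
    dem, _ = read_grid(directory / "dem.tif", spec)
    roads = read_roads(directory / "roads.geojson")
    zones = read_zones(directory / "zones.geojson")
    ref = None
    if (directory / "reference_loss.tif").exists():
        ref, _ = read_grid(directory / "reference_loss.tif", spec)

    gt = pd.read_csv(directory / "ground_truth.csv")
    area_ha = spec.pixel_area_ha
    mtb = np.divide(upper.bph, upper.tph, out=np.zeros(spec.shape), where=upper.tph > 0)
    dt_by_year = {t: np.zeros(spec.shape) for t in config.years}
    dbm_by_year = {t: np.zeros(spec.shape) for t in config.years}
    per_polygon = []
    if len(gt):
        for (pid, year), grp in gt.groupby(["polygon_id", "year"], sort=False):
            r = grp["row"].to_numpy()
            c = grp["col"].to_numpy()
            dt = grp["dt_true"].to_numpy()
            dbm = grp["dbm_true"].to_numpy()
            per_polygon.append(PolygonTruth(str(pid), int(year), r, c, dt, dbm))
            dt_by_year[int(year)][r, c] += dt
            dbm_by_year[int(year)][r, c] += dbm
    total_dbm = sum(dbm_by_year.values()) if config.years else np.zeros(spec.shape)
    truth = GroundTruth(
        variant=upper.variant,
        spec=spec,
        dt_by_year=dt_by_year,
        dbm_by_year=dbm_by_year,
        tdbm=np.minimum(total_dbm, upper.bph * area_ha),
        per_polygon=per_polygon,
    )
    return Bundle(
        config=config,
        structure_upper=upper,
        structure_lower=lower,
        polygons=polys,
        truth=truth,
        dem=dem,
        roads=roads,
        zones=zones,
        reference_loss=ref,
    )
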