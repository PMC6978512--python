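"""Shared geospatial data model and I/O primitives.

All layers in an analysis live on a single pixel-aligned grid in one
projected, metric coordinate reference system (CRS).  Rasters are stored
as GeoTIFFs (georeferencing written via the ModelPixelScale and
ModelTiepoint tags, plus a JSON image description that round-trips the
full :class:`GridSpec`); vector layers are stored as GeoJSON.

Conventions
-----------
* row 0 is the northernmost row; pixel indices are 0-based;
* a pixel belongs to a polygon when its *center* lies inside or on the
  boundary of the polygon;
* distances are straight-line (Euclidean) in the projected plane;
* no on-the-fly reprojection: layers on mismatched grids raise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GeodataError",
    "GridAlignmentError",
    "GridSpec",
    "StructureGrid",
    "MortalityPolygon",
    "RoadNetwork",
    "ZoneSet",
    "read_grid",
    "write_grid",
    "pixels_in_polygon",
    "distance_to_nearest_road",
    "read_feature_collection",
    "write_feature_collection",
    "read_mortality",
    "write_mortality",
    "read_roads",
    "write_roads",
    "read_zones",
    "write_zones",
    "read_structure",
    "write_structure",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


class GeodataError(Exception):
    """Base class for geodata failures."""


class GridAlignmentError(GeodataError):
    """A layer does not share the expected grid (origin, pixel size, shape or CRS)."""


@dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a pixel-aligned raster grid.

    ``origin_x``/``origin_y`` are the projected coordinates (meters) of the
    *top-left corner* of pixel (0, 0).  With the default 30 m pixel, each
    pixel covers 900 m**2 = 0.09 ha.
    """

    origin_x: float
    origin_y: float
    n_rows: int
    n_cols: int
    pixel_size: float = 30.0
    crs_id: str = "LOCAL_METRIC"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive extent")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size**2

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 1e4

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_size

    def center_of(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Projected coordinates of pixel centers for given row/col indices."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = self.origin_x + (cols + 0.5) * self.pixel_size
        y = self.origin_y - (rows + 0.5) * self.pixel_size
        return x, y

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pixel_size": self.pixel_size,
            "crs_id": self.crs_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass
class StructureGrid:
    """Live forest-structure layers for one detection-threshold variant.

    ``variant`` tags the tree-size subset the layers describe:
    ``"dbh_ge_25cm"`` (trees >= 25 cm diameter at breast height, the
    aerial-detection upper bound) or ``"dbh_ge_2p5cm"`` (all trees
    >= 2.5 cm DBH, the lower bound).  ``tph``/``bph``/``vph`` are live
    trees, live aboveground biomass (bone-dry tons) and live stem volume
    (m**3) per hectare.
    """

    spec: GridSpec
    variant: str
    tph: np.ndarray
    bph: np.ndarray
    vph: np.ndarray
    forest_mask: np.ndarray

    VARIANTS = ("dbh_ge_25cm", "dbh_ge_2p5cm")

    def __post_init__(self) -> None:
        if self.variant not in self.VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("tph", "bph", "vph", "forest_mask"):
            arr = getattr(self, name)
            if arr.shape != self.spec.shape:
                raise GridAlignmentError(f"{name} shape {arr.shape} != grid {self.spec.shape}")

    def validate(self) -> None:
        """Check structural invariants; raises ``GeodataError`` on violation."""
        if np.any(self.tph < 0) or np.any(self.bph < 0) or np.any(self.vph < 0):
            raise GeodataError("negative structure values")
        if np.any((self.bph > 0) & (self.tph <= 0)):
            raise GeodataError("biomass present where tree density is zero")
        if np.any((self.vph > 0) & (self.tph <= 0)):
            raise GeodataError("volume present where tree density is zero")
        nf = ~self.forest_mask.astype(bool)
        if np.any(self.tph[nf] != 0) or np.any(self.bph[nf] != 0) or np.any(self.vph[nf] != 0):
            raise GeodataError("non-forest pixels carry structure values")


@dataclass
class MortalityPolygon:
    """One aerial-survey mortality polygon: a year and a dead-tree count.

    ``dead_trees`` may be fractional (surveyed counts are estimates and the
    allocation arithmetic is continuous).
    """

    polygon_id: str
    year: int
    geometry: BaseGeometry
    dead_trees: float

    def __post_init__(self) -> None:
        if self.dead_trees < 0:
            raise ValueError("dead_trees must be >= 0")
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise GeodataError(f"polygon {self.polygon_id}: invalid or empty geometry")


@dataclass
class RoadNetwork:
    lines: list[BaseGeometry] = field(default_factory=list)

    def union(self) -> BaseGeometry | None:
        if not self.lines:
            return None
        return shapely.union_all(self.lines)


@dataclass
class ZoneSet:
    """Administrative overlays: wilderness/National Park (harvest excluded),
    High Hazard Zone tiers 1 and 2 (which may overlap), and counties."""

    wilderness_np: list[BaseGeometry] = field(default_factory=list)
    hhz_tier1: list[BaseGeometry] = field(default_factory=list)
    hhz_tier2: list[BaseGeometry] = field(default_factory=list)
    counties: dict[str, BaseGeometry] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def write_grid(path: str | Path, data: np.ndarray, spec: GridSpec) -> None:
    """Write a single-band raster as a georeferenced TIFF.

    Biomass-type layers should be float64; masks uint8.  Georeferencing is
    carried both in standard GeoTIFF tags and in a JSON description.
    """
    data = np.asarray(data)
    if data.shape != spec.shape:
        raise GridAlignmentError(f"data shape {data.shape} != grid {spec.shape}")
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (spec.pixel_size, spec.pixel_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0)),
    ]
    tifffile.imwrite(
        str(path),
        data,
        description=json.dumps({"grid_spec": spec.to_dict()}),
        extratags=extratags,
    )


def _spec_from_tiff(page: "tifffile.TiffPage", path: Path) -> GridSpec:
    desc = page.tags.get("ImageDescription")
    if desc is not None:
        try:
            meta = json.loads(desc.value)
            if "grid_spec" in meta:
                return GridSpec.from_dict(meta["grid_spec"])
        except (json.JSONDecodeError, TypeError):
            pass
    scale = page.tags.get(_MODEL_PIXEL_SCALE)
    tie = page.tags.get(_MODEL_TIEPOINT)
    if scale is None or tie is None:
        raise GeodataError(f"{path}: no georeferencing tags")
    sx, sy = scale.value[0], scale.value[1]
    if not np.isclose(sx, sy):
        raise GeodataError(f"{path}: anisotropic pixels unsupported")
    return GridSpec(
        origin_x=tie.value[3],
        origin_y=tie.value[4],
        n_rows=page.imagelength,
        n_cols=page.imagewidth,
        pixel_size=sx,
        crs_id="LOCAL_METRIC",
    )


def read_grid(
    path: str | Path, expected_spec: GridSpec | None = None
) -> tuple[np.ndarray, GridSpec]:
    """Read a single-band georeferenced raster.

    When ``expected_spec`` is given, the file's grid must match it exactly
    (origin, pixel size, shape and CRS) or :class:`GridAlignmentError` is
    raised — there is no resampling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        spec = _spec_from_tiff(page, path)
    if expected_spec is not None and spec != expected_spec:
        raise GridAlignmentError(f"{path}: grid {spec} does not match expected {expected_spec}")
    return data, spec


# ---------------------------------------------------------------------------
# Raster/vector overlay primitives
# ---------------------------------------------------------------------------

def pixels_in_polygon(geometry: BaseGeometry, spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices whose centers fall inside or on the boundary of a polygon.

    Returns ``(rows, cols)`` integer arrays in row-major order.  A polygon
    disjoint from the grid yields empty arrays.  The center-containment rule
    makes any polygonal partition of the extent cover each pixel exactly once
    (up to boundary ties, which go to whichever partition member the shared
    edge belongs to — both, for ``intersects`` semantics, so partitions should
    use half-open edges if strict single-coverage matters).
    """
    if not geometry.is_valid:
        raise GeodataError("invalid geometry")
    if geometry.is_empty:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    minx, miny, maxx, maxy = geometry.bounds
    px = spec.pixel_size
    # candidate index window from the bounding box
    c0 = max(int(np.floor((minx - spec.origin_x) / px - 0.5)), 0)
    c1 = min(int(np.ceil((maxx - spec.origin_x) / px - 0.5)), spec.n_cols - 1)
    r0 = max(int(np.floor((spec.origin_y - maxy) / px - 0.5)), 0)
    r1 = min(int(np.ceil((spec.origin_y - miny) / px - 0.5)), spec.n_rows - 1)
    if c1 < c0 or r1 < r0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rows, cols = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    rows = rows.ravel()
    cols = cols.ravel()
    x, y = spec.center_of(rows, cols)
    inside = shapely.intersects_xy(geometry, x, y)
    return rows[inside], cols[inside]


def distance_to_nearest_road(
    x: float | np.ndarray, y: float | np.ndarray, roads: RoadNetwork
) -> np.ndarray:
    """Straight-line distance (m) from point(s) to the nearest road line.

    An empty network means "no road": every distance is ``inf`` so all
    pixels classify beyond any cutoff.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    merged = roads.union()
    if merged is None or merged.is_empty:
        return np.full(x.shape, np.inf)
    pts = shapely.points(x, y)
    return shapely.distance(pts, merged)


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def write_feature_collection(
    path: str | Path,
    geometries: Iterable[BaseGeometry],
    properties: Iterable[dict],
    crs_id: str,
) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties)
    ]
    fc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs_id}},
        "features": features,
    }
    Path(path).write_text(json.dumps(fc))


def read_feature_collection(path: str | Path) -> tuple[list[BaseGeometry], list[dict], str]:
    fc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    props = [f.get("properties") or {} for f in fc["features"]]
    crs_id = fc.get("crs", {}).get("properties", {}).get("name", "LOCAL_METRIC")
    return geoms, props, crs_id


def write_mortality(path: str | Path, polys: Sequence[MortalityPolygon], crs_id: str) -> None:
    write_feature_collection(
        path,
        [p.geometry for p in polys],
        [
            {"polygon_id": p.polygon_id, "year": p.year, "dead_trees": p.dead_trees}
            for p in polys
        ],
        crs_id,
    )


def read_mortality(path: str | Path) -> list[MortalityPolygon]:
    geoms, props, _ = read_feature_collection(path)
    return [
        MortalityPolygon(
            polygon_id=str(p["polygon_id"]),
            year=int(p["year"]),
            geometry=g,
            dead_trees=float(p["dead_trees"]),
        )
        for g, p in zip(geoms, props)
    ]


def write_roads(path: str | Path, roads: RoadNetwork, crs_id: str) -> None:
    write_feature_collection(path, roads.lines, [{} for _ in roads.lines], crs_id)


def read_roads(path: str | Path) -> RoadNetwork:
    geoms, _, _ = read_feature_collection(path)
    return RoadNetwork(lines=geoms)


def write_zones(path: str | Path, zones: ZoneSet, crs_id: str) -> None:
    geoms: list[BaseGeometry] = []
    props: list[dict] = []
    for g in zones.wilderness_np:
        geoms.append(g)
        props.append({"zone_type": "wilderness_np"})
    for g in zones.hhz_tier1:
        geoms.append(g)
        props.append({"zone_type": "hhz_tier1"})
    for g in zones.hhz_tier2:
        geoms.append(g)
        props.append({"zone_type": "hhz_tier2"})
    for name, g in zones.counties.items():
        geoms.append(g)
        props.append({"zone_type": "county", "name": name})
    write_feature_collection(path, geoms, props, crs_id)


def read_zones(path: str | Path) -> ZoneSet:
    geoms, props, _ = read_feature_collection(path)
    zones = ZoneSet()
    for g, p in zip(geoms, props):
        zt = p.get("zone_type")
        if zt == "wilderness_np":
            zones.wilderness_np.append(g)
        elif zt == "hhz_tier1":
            zones.hhz_tier1.append(g)
        elif zt == "hhz_tier2":
            zones.hhz_tier2.append(g)
        elif zt == "county":
            zones.counties[p["name"]] = g
        else:
            raise GeodataError(f"unknown zone_type {zt!r}")
    return zones


_LAYERS = ("tph", "bph", "vph", "forest_mask")


def write_structure(directory: str | Path, sg: StructureGrid) -> None:
    """Write one structure variant as four GeoTIFFs in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _LAYERS:
        arr = getattr(sg, name)
        if name == "forest_mask":
            arr = arr.astype(np.uint8)
        else:
            arr = arr.astype(np.float64)
        write_grid(directory / f"structure_{sg.variant}_{name}.tif", arr, sg.spec)


def read_structure(
    directory: str | Path, variant: str, expected_spec: GridSpec | None = None
) -> StructureGrid:
    directory = Path(directory)
    layers = {}
    spec = expected_spec
    for name in _LAYERS:
        arr, file_spec = read_grid(directory / f"structure_{variant}_{name}.tif", spec)
        spec = file_spec
        layers[name] = arr
    layers["forest_mask"] = layers["forest_mask"].astype(bool)
    return StructureGrid(spec=spec, variant=variant, **layers)
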