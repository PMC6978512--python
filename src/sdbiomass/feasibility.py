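"""Harvest-feasibility screening of the dead-biomass grid.

Four sequential, contractive filters remove biomass that cannot
realistically be recovered for bioenergy:

1. **Spatial isolation** — DBSCAN over the centers of pixels carrying dead
   biomass, with a minimum cluster size of 112 pixels (~10 ha at 0.09
   ha/pixel).  Pixels left as noise are dropped.  The expansion radius
   (eps) is chosen at the knee of a trade-off curve between biomass removed
   and mean cluster compactness (standard distance).  At 30-m spacing no
   cluster can form below eps = 180 m: only 109 lattice centers fit inside
   a 179-m radius, while 113 fit inside 180 m.
2. **Wilderness / National Park** — mechanical harvest excluded by law.
3. **Maximum mean tree volume** — pixels whose mean volume per tree (VPT =
   VPH/TPH) is >= 11.32 m^3 exceed facility chipping in-feed limits.
4. **Minimum dead-tree density** — areas below 2.5 dead trees/ha are too
   sparse to harvest selectively.

Filter order is fixed (isolation -> wilderness -> VPT/density) because the
removed-biomass attribution of a cascade depends on order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from sklearn.cluster import DBSCAN

from .allocation import DeadBiomassGrid
from .geodata import StructureGrid, ZoneSet

__all__ = [
    "DEFAULT_MIN_PTS",
    "DEFAULT_EPS_SWEEP",
    "VPT_MAX",
    "MIN_DEAD_DENSITY",
    "ClusterAssignment",
    "dbscan",
    "standard_distance",
    "tradeoff_curve",
    "select_eps",
    "filter_isolated",
    "filter_zones",
    "mean_tree_volume",
    "vpt_density_drop_mask",
    "filter_vpt_and_density",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_PTS = 112  # pixels per cluster, ~10 ha
DEFAULT_EPS_SWEEP = tuple(range(180, 401, 20))  # m
VPT_MAX = 11.32  # m^3/tree, facility chipping limit
MIN_DEAD_DENSITY = 2.5  # dead trees per ha


@dataclass
class ClusterAssignment:
    """DBSCAN result over pixel centers.

    ``labels`` follows scikit-learn conventions: -1 marks noise.  The
    neighborhood of a point includes the point itself, so a core point
    needs ``min_pts`` total points (itself plus min_pts - 1 others) within
    eps.  Core/noise status is order-independent; the cluster id a border
    point joins is resolved by the deterministic row-major scan order of
    the input.
    """

    rows: np.ndarray
    cols: np.ndarray
    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray
    min_pts: int
    eps: float

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    def noise_mask(self) -> np.ndarray:
        return self.labels < 0

    def cluster_standard_distances(self) -> dict[int, float]:
        out = {}
        for cid in sorted(set(self.labels[self.labels >= 0])):
            m = self.labels == cid
            out[int(cid)] = standard_distance(self.x[m], self.y[m])
        return out


def dbscan(
    rows: np.ndarray,
    cols: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    eps: float,
    min_pts: int = DEFAULT_MIN_PTS,
) -> ClusterAssignment:
    """Standard DBSCAN over pixel centers (Euclidean metric).

    Points within exactly ``eps`` of a core point are neighbors (closed
    ball).  An empty point set yields an empty assignment.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        labels = np.empty(0, dtype=int)
    else:
        labels = DBSCAN(eps=eps, min_samples=min_pts).fit(np.column_stack([x, y])).labels_
    return ClusterAssignment(rows=rows, cols=cols, x=x, y=y, labels=labels, min_pts=min_pts, eps=eps)


def standard_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Dispersion of a point set about its centroid (m).

    SD = sqrt( mean((x - xbar)^2) + mean((y - ybar)^2) ), using population
    moments; a single point has SD = 0.  Translation invariant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("standard distance of an empty point set is undefined")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2) + np.mean((y - y.mean()) ** 2)))


def _sd_points(grid: DeadBiomassGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    rows, cols = np.nonzero(grid.tdbm > 0)
    x, y = grid.spec.center_of(rows, cols)
    return rows, cols, x, y


def tradeoff_curve(
    grid: DeadBiomassGrid,
    eps_values: tuple[float, ...] = DEFAULT_EPS_SWEEP,
    min_pts: int = DEFAULT_MIN_PTS,
) -> pd.DataFrame:
    """Sweep eps and record (biomass removed as noise, mean cluster compactness).

    Removed biomass is non-increasing in eps (reachability only grows);
    this is asserted on every run.  With zero clusters the mean standard
    distance is undefined and recorded as NaN.
    """
    eps_values = tuple(eps_values)
    if any(b <= a for a, b in zip(eps_values, eps_values[1:])):
        raise ValueError("eps_values must be strictly increasing")
    rows, cols, x, y = _sd_points(grid)
    tdbm = grid.tdbm[rows, cols]
    records = []
    for eps in eps_values:
        assign = dbscan(rows, cols, x, y, eps=eps, min_pts=min_pts)
        noise = assign.noise_mask()
        sds = assign.cluster_standard_distances()
        records.append(
            {
                "eps": float(eps),
                "biomass_removed": float(tdbm[noise].sum()),
                "mean_standard_distance": float(np.mean(list(sds.values()))) if sds else np.nan,
                "n_clusters": assign.n_clusters,
            }
        )
    curve = pd.DataFrame(records)
    removed = curve["biomass_removed"].to_numpy()
    if np.any(np.diff(removed) > 1e-9 * max(removed.max(), 1.0)):
        raise AssertionError("removed biomass must be non-increasing in eps")
    return curve


def select_eps(curve: pd.DataFrame) -> float:
    """Pick eps at the knee of the trade-off curve.

    The curve (mean standard distance, biomass removed) is min-max
    normalized on both axes and the point of maximum discrete (Menger)
    curvature is taken; ties and the all-linear degenerate case resolve
    toward the smallest interior eps, since a smaller eps yields more
    compact clusters.
    """
    ok = curve.dropna(subset=["mean_standard_distance", "biomass_removed"])
    if len(ok) < 3:
        raise ValueError("need at least 3 defined curve points to select eps")
    u = ok["mean_standard_distance"].to_numpy(dtype=float)
    v = ok["biomass_removed"].to_numpy(dtype=float)
    eps = ok["eps"].to_numpy(dtype=float)

    def norm(a: np.ndarray) -> np.ndarray:
        rng = a.max() - a.min()
        return (a - a.min()) / rng if rng > 0 else np.zeros_like(a)

    u, v = norm(u), norm(v)
    kappa = np.zeros(len(eps))
    for k in range(1, len(eps) - 1):
        p0 = np.array([u[k - 1], v[k - 1]])
        p1 = np.array([u[k], v[k]])
        p2 = np.array([u[k + 1], v[k + 1]])
        a = np.linalg.norm(p1 - p0)
        b = np.linalg.norm(p2 - p1)
        c = np.linalg.norm(p2 - p0)
        if a * b * c == 0:
            continue
        cross = abs((p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0]))
        kappa[k] = 2.0 * cross / (a * b * c)
    interior = kappa[1:-1]
    if interior.size == 0 or np.all(interior <= 1e-12):
        log.warning("trade-off curve has no curvature; falling back to smallest interior eps")
        return float(eps[1])
    k_best = 1 + int(np.argmax(interior))  # argmax returns first (smallest-eps) tie
    return float(eps[k_best])


def filter_isolated(
    grid: DeadBiomassGrid, assignment: ClusterAssignment
) -> tuple[DeadBiomassGrid, float]:
    """Zero cumulative dead biomass on noise pixels; report the biomass removed."""
    out = grid.copy()
    noise = assignment.noise_mask()
    r, c = assignment.rows[noise], assignment.cols[noise]
    removed = float(out.tdbm[r, c].sum())
    out.tdbm[r, c] = 0.0
    return out, removed


def filter_zones(grid: DeadBiomassGrid, zones: ZoneSet) -> tuple[DeadBiomassGrid, float]:
    """Zero biomass on pixels whose centers fall in wilderness/National Park."""
    out = grid.copy()
    if not zones.wilderness_np:
        return out, 0.0
    rows, cols = np.nonzero(out.tdbm > 0)
    if rows.size == 0:
        return out, 0.0
    x, y = out.spec.center_of(rows, cols)
    excluded = shapely.union_all(zones.wilderness_np)
    inside = shapely.intersects_xy(excluded, x, y)
    removed = float(out.tdbm[rows[inside], cols[inside]].sum())
    out.tdbm[rows[inside], cols[inside]] = 0.0
    return out, removed


def mean_tree_volume(structure: StructureGrid) -> np.ndarray:
    """Mean live stem volume per tree, VPT = VPH/TPH (m^3); 0 where TPH = 0.

    Pixels with TPH = 0 have no defined VPT and carry no dead biomass, so
    the 0 placeholder never reaches a threshold comparison downstream.
    """
    return np.divide(
        structure.vph, structure.tph, out=np.zeros(structure.spec.shape), where=structure.tph > 0
    )


def vpt_density_drop_mask(
    grid: DeadBiomassGrid,
    vpt: np.ndarray,
    vpt_max: float = VPT_MAX,
    min_dead_density: float = MIN_DEAD_DENSITY,
) -> np.ndarray:
    """Boolean mask of pixels failing the tree-size or dead-density screens."""
    dead_density = grid.total_dt() / grid.spec.pixel_area_ha
    return (vpt >= vpt_max) | (dead_density < min_dead_density)


def filter_vpt_and_density(
    grid: DeadBiomassGrid,
    vpt: np.ndarray,
    vpt_max: float = VPT_MAX,
    min_dead_density: float = MIN_DEAD_DENSITY,
    drop_mask: np.ndarray | None = None,
) -> tuple[DeadBiomassGrid, float]:
    """Drop oversized-tree pixels and very sparse mortality.

    A pixel is removed when VPT >= ``vpt_max`` (inclusive: a mean tree at
    exactly the in-feed limit cannot be chipped) OR its cumulative dead-tree
    density, sum_t DT / 0.09 ha, is strictly below ``min_dead_density``
    (a pixel at exactly the density cutoff is retained).  ``drop_mask``
    lets a caller reuse one variant's screen on the other so both bounds
    describe a single spatial footprint.
    """
    out = grid.copy()
    if drop_mask is None:
        drop_mask = vpt_density_drop_mask(grid, vpt, vpt_max, min_dead_density)
    drop = (out.tdbm > 0) & drop_mask
    removed = float(out.tdbm[drop].sum())
    out.tdbm[drop] = 0.0
    return out, removed
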