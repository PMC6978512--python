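"""Feasibility screening: DBSCAN semantics, trade-off knee, filter bookkeeping."""

import logging

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from sdbiomass.allocation import run_allocation
from sdbiomass.feasibility import (
    dbscan,
    filter_isolated,
    filter_zones,
    mean_tree_volume,
    select_eps,
    standard_distance,
    tradeoff_curve,
    filter_vpt_and_density,
)
from sdbiomass.geodata import GridSpec, ZoneSet
from sdbiomass.synthetic import generate_bundle

from conftest import small_config


def brute_force_dbscan(x, y, eps, min_pts):
    """Independent reference: explicit density-reachability expansion.

    Returns (labels, core_mask) with noise = -1.  Border points join the
    first cluster (in scan order) from which they are reachable, matching
    deterministic scan-order semantics.
    """
    n = x.size
    d2 = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
    neighbors = d2 <= eps**2  # closed ball; includes the point itself
    core = neighbors.sum(axis=1) >= min_pts
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # BFS over core points
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in np.nonzero(neighbors[j])[0]:
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    return labels, core


def lattice_neighbor_count(eps_m, pixel_m=30.0):
    """Number of lattice centers (incl. the origin) within eps of a center."""
    r = int(np.ceil(eps_m / pixel_m))
    count = 0
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            if (i * i + j * j) * pixel_m**2 <= eps_m**2:
                count += 1
    return count


class TestDbscan:
    def test_matches_brute_force_on_random_instances(self, rng):
        """Core/noise status and cluster partition match an exhaustive oracle."""
        for trial in range(5):
            n = int(rng.integers(50, 300))
            x = rng.uniform(0, 2000, n)
            y = rng.uniform(0, 2000, n)
            eps = float(rng.uniform(80, 300))
            min_pts = int(rng.integers(3, 12))
            ours = dbscan(np.zeros(n, int), np.zeros(n, int), x, y, eps, min_pts)
            ref_labels, _ = brute_force_dbscan(x, y, eps, min_pts)
            # identical noise sets
            np.testing.assert_array_equal(ours.labels < 0, ref_labels < 0)
            # identical partition up to label renaming (core points determine it)
            for lab in set(ref_labels[ref_labels >= 0]):
                members = ref_labels == lab
                ours_labs = set(ours.labels[members])
                # border-point ties aside, each reference cluster maps into
                # clusters whose cores coincide; require equality of partitions
                assert len(ours_labs) == 1

    def test_lattice_neighbor_arithmetic(self):
        # 113 centers within 180 m on a 30-m lattice; only 109 within 179 m
        assert lattice_neighbor_count(180.0) == 113
        assert lattice_neighbor_count(179.0) == 109

    def test_min_cluster_size_threshold_on_full_lattice(self):
        """min_pts=112 clusters form at eps=180 m but not at 179 m on a full grid."""
        spec = GridSpec(origin_x=0.0, origin_y=30.0 * 25, n_rows=25, n_cols=25)
        rows, cols = np.meshgrid(np.arange(25), np.arange(25), indexing="ij")
        rows, cols = rows.ravel(), cols.ravel()
        x, y = spec.center_of(rows, cols)
        at180 = dbscan(rows, cols, x, y, eps=180.0, min_pts=112)
        assert at180.n_clusters >= 1
        at179 = dbscan(rows, cols, x, y, eps=179.0, min_pts=112)
        assert at179.n_clusters == 0 and np.all(at179.noise_mask())

    def test_group_below_min_pts_is_all_noise(self, rng):
        x = rng.uniform(0, 50, 111)  # coincidentally tight cluster of 111 points
        y = rng.uniform(0, 50, 111)
        out = dbscan(np.zeros(111, int), np.zeros(111, int), x, y, eps=500.0, min_pts=112)
        assert np.all(out.noise_mask())

    def test_empty_point_set(self):
        out = dbscan(np.empty(0, int), np.empty(0, int), np.empty(0), np.empty(0), 100.0, 5)
        assert out.labels.size == 0 and out.n_clusters == 0

    def test_order_invariance_of_core_noise_status(self, rng):
        n = 200
        x = rng.uniform(0, 1000, n)
        y = rng.uniform(0, 1000, n)
        perm = rng.permutation(n)
        a = dbscan(np.zeros(n, int), np.zeros(n, int), x, y, 120.0, 5)
        b = dbscan(np.zeros(n, int), np.zeros(n, int), x[perm], y[perm], 120.0, 5)
        noise_a = set(map(tuple, np.column_stack([a.x, a.y])[a.noise_mask()]))
        noise_b = set(map(tuple, np.column_stack([b.x, b.y])[b.noise_mask()]))
        assert noise_a == noise_b


class TestStandardDistance:
    def test_single_point_is_zero(self):
        assert standard_distance(np.array([5.0]), np.array([7.0])) == 0.0

    def test_square_corners_hand_value(self):
        x = np.array([-15.0, 15.0, 15.0, -15.0])
        y = np.array([-15.0, -15.0, 15.0, 15.0])
        # sqrt(225 + 225) = 21.2132...
        assert standard_distance(x, y) == pytest.approx(np.sqrt(450.0))

    def test_translation_invariance(self, rng):
        x = rng.uniform(0, 100, 40)
        y = rng.uniform(0, 100, 40)
        assert standard_distance(x + 1234.5, y - 987.0) == pytest.approx(
            standard_distance(x, y)
        )

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            standard_distance(np.empty(0), np.empty(0))


class TestTradeoffCurve:
    def test_removed_biomass_monotone_non_increasing(self, default_result):
        curve = default_result.tradeoff
        removed = curve["biomass_removed"].to_numpy()
        assert np.all(np.diff(removed) <= 1e-9 * max(removed.max(), 1.0))

    def test_eps_values_must_increase(self, small_bundle):
        b = small_bundle
        gu, _ = run_allocation(b.polygons, b.structure_upper, b.structure_lower)
        with pytest.raises(ValueError):
            tradeoff_curve(gu, eps_values=(200.0, 200.0))

    def test_removed_drops_at_formation_threshold(self, small_bundle):
        b = small_bundle
        gu, _ = run_allocation(b.polygons, b.structure_upper, b.structure_lower)
        curve = tradeoff_curve(gu, eps_values=(100.0, 179.0, 180.0, 400.0), min_pts=112)
        # below the lattice bound everything is noise
        total = gu.tdbm.sum()
        assert curve.loc[0, "biomass_removed"] == pytest.approx(total)
        assert curve.loc[1, "biomass_removed"] == pytest.approx(total)
        assert curve.loc[3, "biomass_removed"] < total


class TestSelectEps:
    @staticmethod
    def _curve(eps, sd, removed):
        return pd.DataFrame(
            {"eps": eps, "mean_standard_distance": sd, "biomass_removed": removed}
        )

    def test_sharp_elbow_is_found(self):
        eps = [180.0, 200.0, 220.0, 240.0, 260.0, 280.0]
        # removed biomass plummets until 220 then flattens; SD grows linearly
        removed = [100.0, 60.0, 20.0, 18.0, 16.0, 14.0]
        sd = [300.0, 320.0, 340.0, 360.0, 380.0, 400.0]
        assert select_eps(self._curve(eps, sd, removed)) == 220.0

    def test_linear_curve_degenerates_to_smallest_interior(self, caplog):
        eps = [180.0, 200.0, 220.0, 240.0]
        with caplog.at_level(logging.WARNING):
            got = select_eps(self._curve(eps, [1.0, 2.0, 3.0, 4.0], [40.0, 30.0, 20.0, 10.0]))
        assert got == 200.0
        assert any("no curvature" in m for m in caplog.messages)

    def test_requires_three_defined_points(self):
        with pytest.raises(ValueError):
            select_eps(self._curve([180.0, 200.0], [1.0, 2.0], [2.0, 1.0]))

    def test_ties_break_toward_smaller_eps(self):
        # symmetric double elbow: equal curvature at 200 and 260
        eps = [180.0, 200.0, 220.0, 240.0, 260.0, 280.0]
        removed = [100.0, 50.0, 45.0, 40.0, 35.0, -15.0]
        sd = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0]
        assert select_eps(self._curve(eps, sd, removed)) == 200.0


class TestFilters:
    def test_all_noise_zeroes_the_grid(self, small_bundle):
        b = small_bundle
        gu, _ = run_allocation(b.polygons, b.structure_upper, b.structure_lower)
        rows, cols = np.nonzero(gu.tdbm > 0)
        x, y = gu.spec.center_of(rows, cols)
        assign = dbscan(rows, cols, x, y, eps=100.0, min_pts=112)  # below lattice bound
        filtered, removed = filter_isolated(gu, assign)
        assert not filtered.tdbm.any()
        assert removed == pytest.approx(gu.tdbm.sum())

    def test_no_noise_is_identity(self, small_bundle):
        b = small_bundle
        gu, _ = run_allocation(b.polygons, b.structure_upper, b.structure_lower)
        rows, cols = np.nonzero(gu.tdbm > 0)
        x, y = gu.spec.center_of(rows, cols)
        assign = dbscan(rows, cols, x, y, eps=1e6, min_pts=2)
        filtered, removed = filter_isolated(gu, assign)
        np.testing.assert_array_equal(filtered.tdbm, gu.tdbm)
        assert removed == 0.0

    def test_zone_filter_bookkeeping(self, small_bundle):
        b = small_bundle
        gu, _ = run_allocation(b.polygons, b.structure_upper, b.structure_lower)
        whole = ZoneSet(wilderness_np=[box(*gu.spec.bounds)])
        filtered, removed = filter_zones(gu, whole)
        assert not filtered.tdbm.any() and removed == pytest.approx(gu.tdbm.sum())
        same, none_removed = filter_zones(gu, ZoneSet())
        np.testing.assert_array_equal(same.tdbm, gu.tdbm)
        assert none_removed == 0.0
        # removed equals the zonal sum for a partial zone
        minx, miny, maxx, maxy = gu.spec.bounds
        west = box(minx, miny, (minx + maxx) / 2, maxy)
        part, rem = filter_zones(gu, ZoneSet(wilderness_np=[west]))
        assert rem == pytest.approx(gu.tdbm.sum() - part.tdbm.sum())

    def test_mean_tree_volume_direct_division_and_guard(self, small_bundle):
        st = small_bundle.structure_upper
        vpt = mean_tree_volume(st)
        pos = st.tph > 0
        np.testing.assert_allclose(vpt[pos], st.vph[pos] / st.tph[pos])
        assert not vpt[~pos].any()

    def test_vpt_threshold_is_inclusive_density_is_strict(self):
        """A mean tree at exactly 11.32 m^3 is removed; exactly 2.5 dead/ha is kept."""
        from sdbiomass.allocation import DeadBiomassGrid
        import pandas as pd

        spec = GridSpec(origin_x=0.0, origin_y=30.0, n_rows=1, n_cols=3)
        tdbm = np.array([[10.0, 10.0, 10.0]])
        dt = np.array([[0.225, 0.225, 0.2249]])  # 2.5, 2.5, <2.5 dead per ha
        vpt = np.array([[11.32, 2.0, 2.0]])
        grid = DeadBiomassGrid(
            spec=spec,
            variant="dbh_ge_25cm",
            dt_by_year={2012: dt},
            dbm_by_year={2012: tdbm.copy()},
            tdbm=tdbm.copy(),
            diagnostics=pd.DataFrame(),
        )
        out, removed = filter_vpt_and_density(grid, vpt)
        assert out.tdbm[0].tolist() == [0.0, 10.0, 0.0]
        assert removed == pytest.approx(20.0)

    def test_filters_are_contractive_in_sequence(self, default_result):
        led = default_result.reduction_ledger
        assert np.all(np.diff(led["upper_total_bdt"]) <= 1e-9)
        assert np.all(np.diff(led["lower_total_bdt"]) <= 1e-9)
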