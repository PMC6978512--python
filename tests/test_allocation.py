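"""Dead-tree allocation: hand-checked shares, caps, conservation, recovery."""

import numpy as np
import pytest
from shapely.geometry import box

from sdbiomass.allocation import (
    accumulate,
    allocate_polygon,
    dead_biomass,
    run_allocation,
)
from sdbiomass.geodata import GridSpec, MortalityPolygon, StructureGrid
from sdbiomass.synthetic import generate_bundle, generate_mortality, generate_structure

from conftest import small_config


def _structure_from_tph(tph_per_ha, bph_per_ha=None, vph_per_ha=None):
    """A 1-row structure grid with the given per-hectare columns."""
    tph = np.asarray([tph_per_ha], dtype=float)
    n = tph.shape[1]
    spec = GridSpec(origin_x=0.0, origin_y=30.0, n_rows=1, n_cols=n)
    bph = np.asarray([bph_per_ha], dtype=float) if bph_per_ha is not None else tph * 2.0
    vph = np.asarray([vph_per_ha], dtype=float) if vph_per_ha is not None else tph * 1.0
    bph[:, tph[0] == 0] = 0.0
    vph[:, tph[0] == 0] = 0.0
    return StructureGrid(
        spec=spec,
        variant="dbh_ge_25cm",
        tph=tph,
        bph=bph,
        vph=vph,
        forest_mask=tph > 0,
    )


def _poly_over(spec, n_cols):
    return box(0.0, 0.0, n_cols * spec.pixel_size, spec.pixel_size)


class TestAllocatePolygon:
    def test_single_pixel_cap_binds(self):
        # 100 trees/ha * 0.09 ha = 9 live trees; a count of 20 caps at 9
        st = _structure_from_tph([100.0])
        poly = MortalityPolygon("p", 2012, _poly_over(st.spec, 1), 20.0)
        _, _, dt, info = allocate_polygon(poly, st)
        assert dt.tolist() == [9.0]
        assert info["allocated"] == 9.0 and info["n_capped"] == 1

    def test_proportional_shares_without_caps(self):
        # shares 30 * {100,200,300}/600 = {5,10,15}; caps {9,18,27} don't bind
        st = _structure_from_tph([100.0, 200.0, 300.0])
        poly = MortalityPolygon("p", 2012, _poly_over(st.spec, 3), 30.0)
        _, _, dt, info = allocate_polygon(poly, st)
        np.testing.assert_allclose(dt, [5.0, 10.0, 15.0])
        assert info["allocated"] == pytest.approx(30.0)

    def test_both_caps_bind_and_surplus_is_not_redistributed(self):
        # shares 40 * {10,300}/310 = {1.2903.., 38.7096..}; caps {0.9, 27}
        st = _structure_from_tph([10.0, 300.0])
        poly = MortalityPolygon("p", 2012, _poly_over(st.spec, 2), 40.0)
        _, _, dt, info = allocate_polygon(poly, st)
        np.testing.assert_allclose(dt, [0.9, 27.0])
        assert info["allocated"] == pytest.approx(27.9)  # < 40: shortfall only logged

    def test_zero_tph_pixels_receive_nothing(self):
        st = _structure_from_tph([0.0, 200.0])
        poly = MortalityPolygon("p", 2012, _poly_over(st.spec, 2), 10.0)
        rows, cols, dt, _ = allocate_polygon(poly, st)
        assert cols.tolist() == [1]
        np.testing.assert_allclose(dt, [10.0])

    def test_unforested_polygon_allocates_nothing_with_diagnostics(self, caplog):
        st = _structure_from_tph([0.0, 0.0])
        poly = MortalityPolygon("p", 2012, _poly_over(st.spec, 2), 5.0)
        with caplog.at_level("WARNING"):
            rows, _, dt, info = allocate_polygon(poly, st)
        assert rows.size == 0 and dt.size == 0
        assert info["requested"] == 5.0 and info["allocated"] == 0.0
        assert any("nothing allocated" in m for m in caplog.messages)

    def test_monotone_in_polygon_count(self):
        st = _structure_from_tph([50.0, 150.0, 250.0])
        geom = _poly_over(st.spec, 3)
        prev = np.zeros(3)
        for count in [5.0, 20.0, 60.0, 200.0]:
            _, _, dt, _ = allocate_polygon(MortalityPolygon("p", 2012, geom, count), st)
            assert np.all(dt >= prev - 1e-12)
            prev = dt

    def test_scale_equivariance_without_caps(self):
        st = _structure_from_tph([100.0, 200.0, 300.0])
        geom = _poly_over(st.spec, 3)
        _, _, dt1, _ = allocate_polygon(MortalityPolygon("p", 2012, geom, 10.0), st)
        _, _, dt2, _ = allocate_polygon(MortalityPolygon("p", 2012, geom, 20.0), st)
        np.testing.assert_allclose(dt2, 2.0 * dt1)
        np.testing.assert_allclose(dead_biomass_at(st, dt2), 2.0 * dead_biomass_at(st, dt1))


def dead_biomass_at(st, dt_vals):
    grid = np.zeros(st.spec.shape)
    grid[0, : dt_vals.size] = dt_vals
    return dead_biomass(grid, st)[0, : dt_vals.size]


class TestDeadBiomass:
    def test_mean_tree_biomass_multiplication(self):
        # 9 dead trees * (200 BDT/ha / 100 trees/ha) = 18 BDT = pixel live biomass
        st = _structure_from_tph([100.0], bph_per_ha=[200.0])
        dt = np.array([[9.0]])
        assert dead_biomass(dt, st)[0, 0] == pytest.approx(18.0)

    def test_zero_dead_trees_give_zero_biomass(self):
        st = _structure_from_tph([100.0])
        assert dead_biomass(np.zeros((1, 1)), st).sum() == 0.0

    def test_saturated_pixel_equals_live_biomass_exactly(self):
        st = _structure_from_tph([123.0], bph_per_ha=[457.0])
        dt = st.tph * st.spec.pixel_area_ha  # fully dead
        np.testing.assert_allclose(dead_biomass(dt, st), st.bph * 0.09)


class TestAccumulate:
    def test_no_correction_when_under_live_biomass(self):
        st = _structure_from_tph([100.0], bph_per_ha=[200.0])
        dbm = {2012: np.array([[5.0]])}
        tdbm, stats = accumulate(dbm, st)
        assert tdbm[0, 0] == 5.0
        assert stats["n_pixels_corrected"] == 0 and stats["biomass_removed"] == 0.0

    def test_two_years_at_sixty_percent_cap_at_live_biomass(self):
        st = _structure_from_tph([100.0], bph_per_ha=[200.0])  # live = 18 BDT/pixel
        sixty = np.array([[0.6 * 18.0]])
        tdbm, stats = accumulate({2012: sixty, 2013: sixty.copy()}, st)
        assert tdbm[0, 0] == pytest.approx(18.0)
        assert stats["n_pixels_corrected"] == 1
        # removed biomass equals sum-over-years minus capped total, exactly
        assert stats["biomass_removed"] == pytest.approx(0.2 * 18.0)

    def test_all_zero_input_gives_all_zero_output(self):
        st = _structure_from_tph([100.0, 0.0])
        tdbm, stats = accumulate({2012: np.zeros((1, 2))}, st)
        assert not tdbm.any() and stats["corrected_fraction"] == 0.0


class TestRunAllocation:
    def test_empty_polygon_list_gives_zero_grids(self):
        cfg = small_config()
        up, lo = generate_structure(cfg)
        gu, gl = run_allocation([], up, lo)
        assert not gu.tdbm.any() and not gl.tdbm.any()

    def test_same_inputs_give_bit_identical_outputs(self, small_bundle):
        b = small_bundle
        r1 = run_allocation(b.polygons, b.structure_upper, b.structure_lower)
        r2 = run_allocation(b.polygons, b.structure_upper, b.structure_lower)
        np.testing.assert_array_equal(r1[0].tdbm, r2[0].tdbm)
        np.testing.assert_array_equal(r1[1].tdbm, r2[1].tdbm)

    def test_upper_bound_exceeds_lower_bound_statewide(self, small_bundle):
        b = small_bundle
        gu, gl = run_allocation(b.polygons, b.structure_upper, b.structure_lower)
        assert gu.tdbm.sum() >= gl.tdbm.sum()

    def test_matches_naive_per_pixel_loop_oracle(self, small_bundle):
        """Vectorized allocation equals an independent scalar-loop evaluation."""
        b = small_bundle
        st = b.structure_upper
        area = st.spec.pixel_area_ha
        gu, _ = run_allocation(b.polygons, st, b.structure_lower)
        for poly in b.polygons[:6]:
            rows, cols, dt, _ = allocate_polygon(poly, st)
            tph_sum = sum(
                st.tph[r, c] for r, c in zip(rows, cols) if st.tph[r, c] > 0
            )
            for r, c, got in zip(rows, cols, dt):
                share = poly.dead_trees * st.tph[r, c] / tph_sum
                expected = min(share, st.tph[r, c] * area)
                assert got == pytest.approx(expected, abs=1e-10)

    def test_proportional_mode_recovers_ground_truth_exactly(self):
        """End-to-end parameter recovery against the generator's retained truth."""
        bundle = generate_bundle(small_config(seed=17))
        gu, _ = run_allocation(bundle.polygons, bundle.structure_upper, bundle.structure_lower)
        scale = max(bundle.truth.tdbm.max(), 1.0)
        for year in bundle.config.years:
            np.testing.assert_allclose(
                gu.dt_by_year[year], bundle.truth.dt_by_year[year], atol=1e-10 * scale
            )
        np.testing.assert_allclose(gu.tdbm, bundle.truth.tdbm, atol=1e-10 * scale)

    def test_size_biased_mode_breaks_exact_recovery(self):
        bundle = generate_bundle(small_config(seed=17, mortality_mode="size_biased"))
        gu, _ = run_allocation(bundle.polygons, bundle.structure_upper, bundle.structure_lower)
        # totals still conserved per polygon ...
        totals = bundle.truth.polygon_totals()
        diag = gu.diagnostics.set_index("polygon_id")
        for pid, t in totals.items():
            assert diag.loc[pid, "requested"] == pytest.approx(t, rel=1e-9)
        # ... but the spatial pattern differs from the (size-biased) truth
        assert not np.allclose(gu.tdbm, bundle.truth.tdbm, rtol=1e-3)

    def test_conservation_with_and_without_caps(self):
        """Sum of allocations never exceeds the survey count; equality iff no cap binds."""
        for seed in range(5):
            bundle = generate_bundle(small_config(seed=seed))
            gu, _ = run_allocation(bundle.polygons, bundle.structure_upper, bundle.structure_lower)
            for _, row in gu.diagnostics.iterrows():
                assert row["allocated"] <= row["requested"] + 1e-9
                if row["n_capped"] == 0:
                    assert row["allocated"] == pytest.approx(row["requested"], rel=1e-9)
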