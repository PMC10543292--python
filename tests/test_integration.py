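"""Regridding, AOD gap-fill, plume rasterisation, labels and the feature table."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, Polygon, box

import smokesep as ss
from smokesep.world import CTMFields, PlumePolygon
from tests.conftest import TINY

GRID = ss.GridSpec(nx=12, ny=10, cell_km=1.0, n_days=4, n_years=1)


class TestIDW:
    def test_constant_field_is_preserved(self, rng):
        nodes = rng.uniform(0, 12, size=(7, 2))
        out = ss.idw_regrid(nodes, np.full(7, 3.5), GRID)
        np.testing.assert_allclose(out, 3.5)

    def test_collocated_query_returns_node_value(self):
        # place one node exactly on a cell center
        nodes = np.array([[2.5, 3.5], [9.0, 9.0]])
        out = ss.idw_regrid(nodes, np.array([42.0, 1.0]), GRID)
        assert out[3, 2] == pytest.approx(42.0)

    def test_matches_hand_rolled_weighted_sum(self, rng):
        nodes = rng.uniform(0, 12, size=(5, 2))
        vals = rng.uniform(1, 9, 5)
        out = ss.idw_regrid(nodes, vals, GRID, power=2.0, k=5)
        q = GRID.cell_centers()[17]
        d = np.hypot(nodes[:, 0] - q[0], nodes[:, 1] - q[1])
        w = d**-2.0
        assert out.ravel()[17] == pytest.approx((w * vals).sum() / w.sum())

    def test_bounded_by_node_range_property(self, rng):
        for _ in range(100):
            n = rng.integers(1, 8)
            nodes = rng.uniform(0, 12, size=(n, 2))
            vals = rng.uniform(-5, 20, n)
            out = ss.idw_regrid(nodes, vals, GRID, k=int(rng.integers(1, 7)))
            assert out.min() >= vals.min() - 1e-9
            assert out.max() <= vals.max() + 1e-9

    def test_k_larger_than_node_count_uses_all(self):
        nodes = np.array([[0.0, 0.0], [12.0, 10.0]])
        out = ss.idw_regrid(nodes, np.array([1.0, 3.0]), GRID, k=10)
        assert np.all((out > 1.0 - 1e-9) & (out < 3.0 + 1e-9))

    def test_daily_stack_matches_per_day_calls(self, rng):
        nodes = rng.uniform(0, 12, size=(6, 2))
        vals = rng.uniform(0, 1, size=(4, 6))
        stacked = ss.idw_regrid(nodes, vals, GRID)
        for d in range(4):
            np.testing.assert_allclose(stacked[d], ss.idw_regrid(nodes, vals[d], GRID))


class TestGapFill:
    def test_no_gaps_pass_through(self, rng):
        aod = rng.uniform(0.05, 0.4, size=(4, 10, 12))
        out = ss.gap_fill_aod(aod, None, {"t": rng.normal(size=(4, 10, 12))})
        np.testing.assert_array_equal(out, aod)

    def test_observed_cells_never_change(self, rng):
        aod = rng.uniform(0.05, 0.4, size=(4, 10, 12))
        gaps = rng.uniform(size=aod.shape) < 0.3
        with_gaps = np.where(gaps, np.nan, aod)
        out = ss.gap_fill_aod(with_gaps, aod * 1.1, None)
        np.testing.assert_array_equal(out[~gaps], aod[~gaps])
        assert not np.isnan(out).any()

    def test_proportional_coarse_field_recovers_truth(self, rng):
        # smooth truth (gap-filling assumes spatial continuity)
        x = np.linspace(0, 1, 12)
        y = np.linspace(0, 1, 10)
        base = 0.2 + 0.1 * np.sin(2 * np.pi * y)[:, None] + 0.1 * x[None, :]
        truth = np.stack([base * s for s in (0.8, 1.0, 1.2, 1.4)])
        coarse = 2.0 * truth  # exactly proportional: regression is exact
        gaps = rng.uniform(size=truth.shape) < 0.2
        out = ss.gap_fill_aod(np.where(gaps, np.nan, truth), coarse, None)
        # step-2 smoothing mixes neighbouring exact values of a smooth field,
        # so the residual is bounded by the field's local variation per cell
        assert np.nanmax(np.abs(out[gaps] - truth[gaps])) < 0.05
        assert np.abs(out[gaps] - truth[gaps]).mean() < 0.02

    def test_needs_some_predictor(self):
        aod = np.full((1, 2, 2), np.nan)
        with pytest.raises(ValueError):
            ss.gap_fill_aod(aod, None, None)


def plume(date=0, poly=None, hours=(6, 12), density=2):
    return PlumePolygon(
        date=date,
        polygon=poly if poly is not None else box(0.0, 0.0, 6.0, 6.0),
        start_hour=hours[0],
        end_hour=hours[1],
        density_class=density,
    )


class TestPlumeFeatures:
    def test_single_plume_identity(self):
        dur, dens = ss.plume_features([plume()], GRID, 0)
        assert dur[2, 2] == 6.0 and dens[2, 2] == 2.0
        assert dur[9, 11] == 0.0 and dens[9, 11] == 0.0

    def test_two_plume_weighting(self):
        plumes = [plume(hours=(6, 12), density=2), plume(hours=(9, 12), density=3)]
        dur, dens = ss.plume_features(plumes, GRID, 0)
        assert dur[2, 2] == pytest.approx(9.0)
        assert dens[2, 2] == pytest.approx((2 * 6 + 3 * 3) / 9)

    def test_no_polygons_on_date(self):
        dur, dens = ss.plume_features([plume(date=3)], GRID, 0)
        assert not dur.any() and not dens.any()

    def test_duration_capped_at_24(self):
        plumes = [plume(hours=(0, 15), density=1), plume(hours=(0, 15), density=1)]
        dur, _ = ss.plume_features(plumes, GRID, 0)
        assert dur.max() == 24.0

    def test_matches_shapely_cover_oracle(self, rng):
        for _ in range(100):
            n_poly = int(rng.integers(1, 4))
            plumes = []
            for _ in range(n_poly):
                cx, cy = rng.uniform(0, 12), rng.uniform(0, 10)
                r = rng.uniform(0.5, 4.0)
                s = int(rng.integers(0, 20))
                plumes.append(
                    plume(poly=Point(cx, cy).buffer(r, quad_segs=3), hours=(s, s + int(rng.integers(1, 5))), density=int(rng.integers(1, 4)))
                )
            dur, dens = ss.plume_features(plumes, GRID, 0)
            centers = GRID.cell_centers()
            i = int(rng.integers(len(centers)))
            pt = Point(*centers[i])
            cover = [p for p in plumes if p.polygon.covers(pt)]
            exp_dur = min(sum(p.duration_hours for p in cover), 24)
            assert dur.ravel()[i] == pytest.approx(exp_dur)
            if cover:
                tot = sum(p.duration_hours for p in cover)
                exp_dens = sum(p.density_class * p.duration_hours for p in cover) / tot
                assert dens.ravel()[i] == pytest.approx(exp_dens)


class TestAssignObservations:
    def test_single_and_multiple_monitors(self):
        obs = pd.DataFrame(
            {
                "site_id": ["a", "b", "c"],
                "x_km": [2.3, 2.7, 8.5],
                "y_km": [3.3, 3.6, 1.5],
                "date": [0, 0, 0],
                "pm25": [10.0, 14.0, 7.0],
            }
        )
        out = ss.assign_observations(obs, GRID)
        cell = out[(out.iy == 3) & (out.ix == 2)]
        assert cell.obs_pm25.iloc[0] == pytest.approx(12.0)  # two monitors averaged
        assert out[(out.iy == 1) & (out.ix == 8)].obs_pm25.iloc[0] == pytest.approx(7.0)

    def test_out_of_grid_site_is_named(self):
        obs = pd.DataFrame(
            {"site_id": ["bad"], "x_km": [99.0], "y_km": [1.0], "date": [0], "pm25": [5.0]}
        )
        with pytest.raises(ValueError, match="bad"):
            ss.assign_observations(obs, GRID)

    def test_group_by_oracle(self, rng):
        n = 100
        obs = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(n)],
                "x_km": rng.uniform(0, 12, n),
                "y_km": rng.uniform(0, 10, n),
                "date": rng.integers(0, 4, n),
                "pm25": rng.uniform(0, 50, n),
            }
        )
        out = ss.assign_observations(obs, GRID)
        # brute-force recount
        iy = np.floor(obs.y_km).astype(int)
        ix = np.floor(obs.x_km).astype(int)
        for _, row in out.iterrows():
            mask = (iy == row.iy) & (ix == row.ix) & (obs.date == row.date)
            assert row.obs_pm25 == pytest.approx(obs.pm25[mask].mean())
        assert len(out) == len(set(zip(obs.date, iy, ix)))


class TestLabelSmoke:
    def ctm_with_background(self, background):
        total = np.full((1, GRID.ny, GRID.nx), 100.0)
        return CTMFields(background=np.full_like(total, background), total=total)

    def test_ratio_above_threshold_labels_smoke(self):
        label = ss.label_smoke([], self.ctm_with_background(96.9), GRID)  # ratio 0.031
        assert label.all()

    def test_ratio_at_threshold_is_no_smoke(self):
        # (100 - 97) / 100 is exactly the 0.03 threshold: strict rule keeps it out
        label = ss.label_smoke([], self.ctm_with_background(97.0), GRID)
        assert not label.any()

    def test_polygon_labels_smoke_even_with_low_ratio(self):
        label = ss.label_smoke([plume()], self.ctm_with_background(98.0), GRID)  # ratio 0.02
        assert label[0, 2, 2] and not label[0, 9, 11]

    def test_matches_brute_force_rule(self, rng):
        for _ in range(100):
            ratio = rng.uniform(0, 0.08, size=(2, GRID.ny, GRID.nx))
            total = np.full_like(ratio, 10.0)
            ctm = CTMFields(background=total * (1 - ratio), total=total)
            plumes = []
            if rng.uniform() < 0.7:
                cx, cy = rng.uniform(0, 12), rng.uniform(0, 10)
                plumes.append(plume(date=int(rng.integers(0, 2)), poly=Point(cx, cy).buffer(rng.uniform(1, 3))))
            label = ss.label_smoke(plumes, ctm, GRID, ratio_threshold=0.03)
            centers = GRID.cell_centers()
            for _ in range(5):
                i = int(rng.integers(len(centers)))
                d = int(rng.integers(0, 2))
                iy, ix = divmod(i, GRID.nx)
                in_poly = any(
                    p.date == d and p.polygon.covers(Point(*centers[i])) for p in plumes
                )
                expected = in_poly or ctm.smoke_ratio[d, iy, ix] > 0.03
                assert label[d, iy, ix] == expected


class TestFeatureTable:
    @pytest.fixture(scope="class")
    def tables(self, tiny_world):
        obs = pd.DataFrame(
            {
                "site_id": ["m1"],
                "x_km": [5.2],
                "y_km": [5.7],
                "date": [0],
                "pm25": [9.0],
                "rh": [50.0],
                "temp_f": [70.0],
                "source": ["reference"],
            }
        )
        return ss.build_feature_table(tiny_world, obs)

    def test_tables_partition_all_cell_days(self, tiny_world, tables):
        smoke, background = tables
        assert len(smoke) + len(background) == tiny_world.grid.n_cells * tiny_world.grid.n_days
        keys = pd.concat([smoke, background])[["date", "iy", "ix"]]
        assert not keys.duplicated().any()

    def test_row_counts_match_label_recount(self, tiny_world, tables):
        smoke, _ = tables
        label = ss.label_smoke(tiny_world.plumes, tiny_world.ctm, tiny_world.grid)
        assert len(smoke) == int(label.sum())

    def test_feature_columns_present(self, tables):
        smoke, background = tables
        for c in ss.SMOKE_FEATURES:
            assert c in smoke.columns
        for c in ss.BACKGROUND_FEATURES:
            assert c in background.columns

    def test_observation_lands_in_its_cell(self, tables):
        smoke, background = tables
        all_rows = pd.concat([smoke, background])
        hit = all_rows[(all_rows.date == 0) & (all_rows.iy == 5) & (all_rows.ix == 5)]
        assert hit.obs_pm25.iloc[0] == pytest.approx(9.0)
        assert all_rows.obs_pm25.notna().sum() == 1

    def test_no_fire_no_error_world_has_empty_smoke_table(self):
        cfg = TINY.with_updates(
            events_per_year=0, ctm_sigma_background=0.0, ctm_sigma_total=0.0, n_lowcost=4
        )
        w = ss.generate_world(cfg, seed=2)
        smoke, background = ss.build_feature_table(w, pd.DataFrame(columns=["site_id", "x_km", "y_km", "date", "pm25"]))
        assert smoke.empty
        assert len(background) == w.grid.n_cells * w.grid.n_days
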