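"""QC screening, pairing, regional GWR fitting and boundary blending."""

import numpy as np
import pandas as pd
import pytest

import smokesep as ss
from smokesep.calibration import OBS_COLUMNS, CalibrationModel, QCRules


def hourly_frame(site="s1", date=0, hours=24, a=7.0, b=7.0, rh=50.0, temp=70.0):
    return pd.DataFrame(
        {
            "site_id": site,
            "date": date,
            "hour": np.arange(hours),
            "pm_a": a,
            "pm_b": b,
            "temp_f": temp,
            "rh": rh,
        }
    )


class TestQCDailyAggregate:
    def test_constant_day_survives_with_channel_mean(self):
        out = ss.qc_daily_aggregate(hourly_frame())
        assert len(out) == 1
        assert out.pm25.iloc[0] == pytest.approx(7.0)
        assert out.source.iloc[0] == "lowcost_raw"

    @pytest.mark.parametrize(
        "frame, reason",
        [
            (hourly_frame(hours=15), "15 hourly pairs"),
            (hourly_frame(a=10.0, b=14.0), "33.3% channel difference"),
            (hourly_frame(a=1200.0, b=1200.0), "daily mean above 1000"),
            (hourly_frame(temp=150.0), "temperature above 140F"),
            (hourly_frame(temp=-30.0), "temperature below -20F"),
            (hourly_frame(rh=105.0), "humidity above 100%"),
        ],
    )
    def test_rule_violations_remove_the_day(self, frame, reason):
        assert ss.qc_daily_aggregate(frame).empty, reason

    def test_sixteen_hours_is_enough(self):
        assert len(ss.qc_daily_aggregate(hourly_frame(hours=16))) == 1

    def test_thirty_percent_difference_is_kept(self):
        # means 10 and 13: |10-13|/11.5 = 26% <= 30%
        out = ss.qc_daily_aggregate(hourly_frame(a=10.0, b=13.0))
        assert len(out) == 1
        assert out.pm25.iloc[0] == pytest.approx(11.5)

    def test_per_channel_completeness(self):
        frame = hourly_frame()
        frame.loc[frame.hour >= 15, "pm_b"] = np.nan  # channel B has only 15 values
        assert ss.qc_daily_aggregate(frame).empty

    def test_empty_input_gives_empty_output(self):
        out = ss.qc_daily_aggregate(pd.DataFrame(columns=hourly_frame().columns))
        assert out.empty and list(out.columns) == OBS_COLUMNS

    def test_idempotent_on_clean_data(self):
        """Re-screening a surviving day's implied hourly data changes nothing."""
        daily = ss.qc_daily_aggregate(hourly_frame(a=9.0, b=10.0, rh=40.0, temp=80.0))
        v = daily.pm25.iloc[0]
        again = ss.qc_daily_aggregate(hourly_frame(a=v, b=v, rh=40.0, temp=80.0))
        assert again.pm25.iloc[0] == pytest.approx(v)


class TestAggregateReference:
    def test_completeness_boundary(self):
        h16 = pd.DataFrame({"site_id": "r", "date": 0, "hour": range(16), "pm25": 5.0})
        h15 = pd.DataFrame({"site_id": "r", "date": 1, "hour": range(15), "pm25": 5.0})
        out = ss.aggregate_reference(pd.concat([h16, h15]))
        assert list(out.date) == [0]

    def test_mean_matches_direct_summation(self, rng):
        vals = rng.uniform(0, 30, 20)
        h = pd.DataFrame({"site_id": "r", "date": 0, "hour": range(20), "pm25": vals})
        out = ss.aggregate_reference(h)
        assert out.pm25.iloc[0] == pytest.approx(vals.sum() / 20)


def daily_obs(site, x, y, dates, pm, rh=50.0, temp=70.0, source="lowcost_raw"):
    dates = np.atleast_1d(dates)
    pm = np.broadcast_to(np.asarray(pm, float), dates.shape)
    return pd.DataFrame(
        {
            "site_id": site,
            "x_km": x,
            "y_km": y,
            "date": dates,
            "pm25": pm,
            "rh": rh,
            "temp_f": temp,
            "source": source,
        }
    )


class TestPairing:
    def test_radius_boundary(self):
        ref = daily_obs("r1", 0.0, 0.0, [0], 10.0, source="reference")
        near = daily_obs("s1", 4.9, 0.0, [0], 12.0)
        far = daily_obs("s2", 5.1, 0.0, [0], 12.0)
        pairs = ss.pair_sensors(pd.concat([near, far]), ref, radius_km=5.0)
        assert list(pairs.site_id) == ["s1"]

    def test_tie_breaks_to_lower_reference_id(self):
        refs = pd.concat(
            [
                daily_obs("r2", 2.0, 0.0, [0], 10.0, source="reference"),
                daily_obs("r1", -2.0, 0.0, [0], 11.0, source="reference"),
            ]
        )
        pairs = ss.pair_sensors(daily_obs("s1", 0.0, 0.0, [0], 12.0), refs)
        assert pairs.ref_site_id.iloc[0] == "r1"

    def test_matches_brute_force_double_loop(self, rng):
        refs = pd.concat(
            [
                daily_obs(f"r{i}", rng.uniform(0, 30), rng.uniform(0, 30), np.arange(10), rng.uniform(5, 15, 10), source="reference")
                for i in range(4)
            ]
        )
        sensors = pd.concat(
            [
                daily_obs(f"s{i}", rng.uniform(0, 30), rng.uniform(0, 30), np.arange(10), rng.uniform(5, 15, 10))
                for i in range(6)
            ]
        )
        pairs = ss.pair_sensors(sensors, refs, radius_km=8.0)

        expected = 0
        ref_sites = refs.drop_duplicates("site_id")
        for _, srow in sensors.drop_duplicates("site_id").iterrows():
            d = np.hypot(ref_sites.x_km - srow.x_km, ref_sites.y_km - srow.y_km)
            if d.min() <= 8.0:
                expected += 10  # all ten dates match
        assert len(pairs) == expected

    def test_three_sensors_all_in_radius(self):
        ref = daily_obs("r1", 0.0, 0.0, np.arange(10), 10.0, source="reference")
        sensors = pd.concat([daily_obs(f"s{i}", 1.0 + i, 0.0, np.arange(10), 12.0) for i in range(3)])
        assert len(ss.pair_sensors(sensors, ref)) == 30


def make_pairs(rng, n=60, ref_fn=None, box=30.0):
    raw = rng.uniform(2, 30, n)
    rh = rng.uniform(20, 90, n)
    temp = rng.uniform(40, 95, n)
    x = rng.uniform(0, box, n)
    y = rng.uniform(0, box, n)
    ref = ref_fn(raw, rh, temp) if ref_fn else raw
    return pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(n)],
            "ref_site_id": "r0",
            "date": 0,
            "x_km": x,
            "y_km": y,
            "raw_pm25": raw,
            "ref_pm25": ref,
            "rh": rh,
            "temp_f": temp,
            "distance_km": 1.0,
        }
    )


class TestGWR:
    def test_exact_linear_world_is_recovered(self, rng):
        pairs = make_pairs(rng, ref_fn=lambda raw, rh, t: 2.0 * raw)
        model = CalibrationModel.fit(1, pairs, bandwidth_km=10.0)
        for q in [(5.0, 5.0), (25.0, 12.0)]:
            beta = model.coefficients_at(*q)
            np.testing.assert_allclose(beta, [0.0, 2.0, 0.0, 0.0], atol=1e-8)
        pred = model.predict(3.0, 3.0, pairs.raw_pm25.to_numpy(), pairs.rh.to_numpy(), pairs.temp_f.to_numpy())
        np.testing.assert_allclose(pred, pairs.ref_pm25, atol=1e-8)

    def test_coefficients_match_weighted_normal_equations(self, rng):
        pairs = make_pairs(rng, ref_fn=lambda raw, rh, t: 1.5 * raw + 0.05 * rh + rng.normal(0, 0.5, len(raw)))
        bw = 12.0
        model = CalibrationModel.fit(1, pairs, bandwidth_km=bw)
        qx, qy = 14.0, 9.0
        beta = model.coefficients_at(qx, qy)

        # independent weighted-normal-equations solve
        d = np.hypot(pairs.x_km - qx, pairs.y_km - qy)
        w = np.exp(-((d / bw) ** 2))
        X = np.column_stack([np.ones(len(pairs)), pairs.raw_pm25, pairs.rh, pairs.temp_f])
        W = np.diag(w)
        beta_direct = np.linalg.solve(X.T @ W @ X, X.T @ W @ pairs.ref_pm25.to_numpy())
        np.testing.assert_allclose(beta, beta_direct, rtol=1e-6)

    def test_infinite_bandwidth_reduces_to_global_ols(self, rng):
        pairs = make_pairs(rng, ref_fn=lambda raw, rh, t: raw + 0.1 * rh)
        model = CalibrationModel.fit(1, pairs, bandwidth_km=1e9)
        b1 = model.coefficients_at(0.0, 0.0)
        b2 = model.coefficients_at(30.0, 30.0)
        np.testing.assert_allclose(b1, b2, rtol=1e-5, atol=1e-8)

    def test_singular_design_reports_region(self, rng):
        pairs = make_pairs(rng)
        pairs["rh"] = 50.0
        pairs["temp_f"] = 70.0  # collinear with intercept
        with pytest.raises(ValueError, match="region 3"):
            CalibrationModel.fit(3, pairs, bandwidth_km=10.0)


class TestCalibrateBlending:
    def setup_method(self):
        grid = ss.GridSpec(nx=100, ny=100, n_days=1, n_years=1)
        self.regions = ss.RegionPartition.quadrants(grid)  # splits at x=50, y=50

    @staticmethod
    def constant_model(region_id, value):
        """A degenerate GWR whose prediction is a constant, for blend tests."""
        m = CalibrationModel.__new__(CalibrationModel)
        m.region_id = region_id
        m.bandwidth_km = 1.0
        m.kernel = "gaussian"
        m.predict = lambda x, y, raw, rh, t, v=value: np.full(np.shape(raw), float(v))
        return m

    def test_interior_sensor_uses_own_region_only(self):
        models = {1: self.constant_model(1, 8.0), 2: self.constant_model(2, 12.0),
                  3: self.constant_model(3, 99.0), 4: self.constant_model(4, 99.0)}
        obs = daily_obs("s1", 20.0, 20.0, [0], 10.0)  # region 1, 30 km from x-split
        out = ss.calibrate(obs, models, self.regions, blend_buffer_km=20.0)
        assert out.pm25.iloc[0] == pytest.approx(8.0)

    def test_buffer_sensor_averages_two_regions(self):
        models = {1: self.constant_model(1, 8.0), 2: self.constant_model(2, 12.0),
                  3: self.constant_model(3, 99.0), 4: self.constant_model(4, 99.0)}
        obs = daily_obs("s1", 40.0, 20.0, [0], 10.0)  # 10 km from region-2 boundary
        out = ss.calibrate(obs, models, self.regions, blend_buffer_km=20.0)
        assert out.pm25.iloc[0] == pytest.approx(10.0)

    def test_corner_sensor_averages_all_adjacent_regions(self):
        models = {r: self.constant_model(r, v) for r, v in zip((1, 2, 3, 4), (4.0, 8.0, 12.0, 16.0))}
        obs = daily_obs("s1", 45.0, 45.0, [0], 10.0)  # near the center corner
        out = ss.calibrate(obs, models, self.regions, blend_buffer_km=20.0)
        assert out.pm25.iloc[0] == pytest.approx(10.0)

    def test_identity_models_pass_values_through(self, rng):
        pairs = make_pairs(rng)  # ref == raw: identity calibration
        models = ss.fit_regional_gwr(pairs, self.regions, bandwidth_km=15.0)
        obs = pd.concat(
            [daily_obs(f"s{i}", rng.uniform(1, 29), rng.uniform(1, 29), np.arange(3), rng.uniform(3, 20, 3)) for i in range(5)]
        )
        out = ss.calibrate(obs, models, self.regions, blend_buffer_km=20.0)
        np.testing.assert_allclose(out.pm25, obs.pm25, atol=1e-6)
        assert (out.pm25 >= 0).all()

    def test_missing_region_model_is_reported(self):
        models = {1: self.constant_model(1, 8.0)}
        obs = daily_obs("s1", 40.0, 20.0, [0], 10.0)  # needs region 2 as well
        with pytest.raises(ValueError, match=r"region\(s\) \[2\]"):
            ss.calibrate(obs, models, self.regions, blend_buffer_km=20.0)


class TestSelectForTraining:
    def test_strict_threshold(self):
        obs = daily_obs("s", 0, 0, np.arange(3), [12.0, 12.1, 5.0])
        kept = ss.select_for_training(obs, threshold=12.0)
        assert list(kept.pm25) == [12.1]

    def test_count_matches_direct_filter(self, rng):
        pm = rng.uniform(0, 24, 100)
        obs = daily_obs("s", 0, 0, np.arange(100), pm)
        assert len(ss.select_for_training(obs)) == int((pm > 12.0).sum())

    def test_empty_input(self):
        assert ss.select_for_training(daily_obs("s", 0, 0, [], [])).empty
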