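"""Generator behaviour: study layout, determinism, closed-form structure,
spatial noise correlation, willows, and out-of-water artifacts."""

import numpy as np
import pandas as pd
import pytest

from meadowtherm.ingest import drop_out_of_water_days
from meadowtherm.metrics import daily_summaries
from meadowtherm.synthetic import (
    build_study,
    default_layout,
    inject_out_of_water,
    reach_mean_wavgt,
    simulate_series,
    simulate_willows,
)
from meadowtherm.types import SimulationParams

from conftest import make_meta


class TestBuildStudy:
    def test_default_layout_matches_deployment(self):
        """30 probes in the partially grazed meadow (17 + 13), 30 and 21 in
        the rested meadows: 81 probes, one series each."""
        probes, series = build_study(SimulationParams(seed=1), years=[2010])
        assert len(probes) == 81
        assert len(series) == 81
        counts = pd.Series([p.reach for p in probes]).value_counts()
        assert counts["Mulkey:grazed"] == 17
        assert counts["Mulkey:ungrazed"] == 13
        assert counts["Ramshaw:ungrazed"] == 30
        assert counts["BigWhitney:ungrazed"] == 21

    def test_record_count_and_span(self):
        probes, series = build_study(
            SimulationParams(seed=1), {"Ramshaw:ungrazed": (2, 100.0)},
            years=[2010], weeks=range(24, 32),
        )
        assert all(len(s) == 8 * 7 * 48 for s in series)
        weeks = series[0].records["timestamp"].dt.isocalendar().week.unique()
        assert set(weeks) == set(range(24, 32))

    def test_deterministic_given_seed(self):
        layout = {"Mulkey:grazed": (3, 200.0)}
        p1, s1 = build_study(SimulationParams(seed=9), layout, years=[2010])
        p2, s2 = build_study(SimulationParams(seed=9), layout, years=[2010])
        assert p1 == p2
        for a, b in zip(s1, s2):
            pd.testing.assert_frame_equal(a.records, b.records)

    def test_one_upstream_probe_per_reach(self):
        probes, _ = build_study(SimulationParams(seed=2), years=[2010])
        df = pd.DataFrame([(p.reach, p.distance_m) for p in probes], columns=["reach", "d"])
        assert (df.groupby("reach")["d"].apply(lambda s: (s == 0).sum()) == 1).all()

    def test_rejects_bad_layouts(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_study(SimulationParams(), {"Mulkey:grazed": (1, 100.0)}, years=[2010])
        with pytest.raises(ValueError, match="length"):
            build_study(SimulationParams(), {"Mulkey:grazed": (3, 0.0)}, years=[2010])
        with pytest.raises(ValueError, match="empty week"):
            build_study(SimulationParams(), years=[2010], weeks=[])


class TestSimulateSeries:
    def test_zero_noise_matches_closed_form(self, quiet_params):
        """With all stochastic terms off the record is exactly
        base + diel sinusoid (flat seasonal, slope 1 disables modulation)."""
        params = quiet_params
        params.seasonal_amplitude = 0.0
        params.max_vs_avg_slope = 1.0
        params.meadow_means = 12.0
        params.gradient_per_100m = 0.3
        params.diel_amplitude_sunny = 5.0
        meta = make_meta(distance_m=200.0, solar_pct=99.0)
        s = simulate_series(meta, params, range(24, 26), 2010)
        hours = s.records["timestamp"].dt.hour + s.records["timestamp"].dt.minute / 60.0
        expected = 12.0 + 0.3 * 2.0 + 5.0 * np.cos(2 * np.pi * (hours - 16.0) / 24.0)
        np.testing.assert_allclose(s.records["temp_c"], expected, atol=1e-10)

    def test_gradient_appears_in_daily_maxima(self, quiet_params):
        """Two noise-free probes 100 m apart differ by exactly the nominal
        gradient (0.41 C) in every daily maximum."""
        params = quiet_params
        params.gradient_per_100m = 0.41
        a = simulate_series(make_meta("A", distance_m=0.0), params, range(24, 28), 2010)
        b = simulate_series(make_meta("B", distance_m=100.0), params, range(24, 28), 2010)
        da, db = daily_summaries(a), daily_summaries(b)
        np.testing.assert_allclose(db["DmaxT"] - da["DmaxT"], 0.41, atol=1e-9)

    def test_solar_threshold_selects_amplitude(self, quiet_params):
        """97% exposure is shaded (range 2x3 C), 99% is sunny (range 2x5 C)."""
        params = quiet_params
        params.diel_amplitude_sunny = 5.0
        params.diel_amplitude_shaded = 3.0
        params.max_vs_avg_slope = 1.0
        shaded = simulate_series(make_meta("A", solar_pct=97.0), params, [25], 2010)
        sunny = simulate_series(make_meta("B", solar_pct=99.0), params, [25], 2010)
        d_sh, d_su = daily_summaries(shaded), daily_summaries(sunny)
        np.testing.assert_allclose(d_sh["DmaxT"] - d_sh["DminT"], 6.0, atol=1e-9)
        np.testing.assert_allclose(d_su["DmaxT"] - d_su["DminT"], 10.0, atol=1e-9)

    def test_identical_metadata_same_deterministic_component(self, quiet_params):
        params = quiet_params
        params.gradient_per_100m = 0.0
        a = simulate_series(make_meta("A"), params, [25], 2010)
        b = simulate_series(make_meta("B"), params, [25], 2010)
        np.testing.assert_array_equal(a.records["temp_c"], b.records["temp_c"])

    def test_rejects_weeks_outside_year(self):
        with pytest.raises(ValueError):
            simulate_series(make_meta(), SimulationParams(), weeks=[0], year=2010)

    def test_reach_mean_closed_form(self, quiet_params):
        """Noise-free reach average of daily means equals the closed form."""
        params = quiet_params
        layout = {"Mulkey:grazed": (5, 400.0)}
        probes, series = build_study(params, layout, years=[2010])
        means = [daily_summaries(s)["DavgT"].mean() for s in series]
        expected = reach_mean_wavgt(params, layout)["Mulkey:grazed"]
        assert np.mean(means) == pytest.approx(expected, abs=1e-6)


class TestSpatialNoise:
    def test_correlation_decays_with_distance(self):
        """Same-time noise correlation between probe pairs decreases
        monotonically across distance bins when spatial_range > 0."""
        layout = {"Ramshaw:ungrazed": (10, 900.0)}
        noisy = SimulationParams(seed=4, spatial_range=200.0, weekly_anomaly_sd=0.0,
                                 probe_offset_sd=0.0)
        clean = SimulationParams(seed=4, spatial_range=200.0, weekly_anomaly_sd=0.0,
                                 probe_offset_sd=0.0, noise_sd=0.0, ar1_phi=0.0)
        _, sn = build_study(noisy, layout, years=[2010])
        _, sc = build_study(clean, layout, years=[2010])
        eps = np.vstack(
            [a.records["temp_c"].to_numpy() - b.records["temp_c"].to_numpy()
             for a, b in zip(sn, sc)]
        )
        pos = np.linspace(0, 900, 10)
        cors, dists = [], []
        for i in range(10):
            for j in range(i + 1, 10):
                cors.append(np.corrcoef(eps[i], eps[j])[0, 1])
                dists.append(abs(pos[i] - pos[j]))
        cors, dists = np.array(cors), np.array(dists)
        bins = [np.mean(cors[dists <= 200]), np.mean(cors[(dists > 200) & (dists <= 500)]),
                np.mean(cors[dists > 500])]
        assert bins[0] > bins[1] > bins[2]

    def test_meadows_have_independent_noise(self):
        """Adding probes in one meadow never perturbs another meadow."""
        base = {"Ramshaw:ungrazed": (3, 200.0)}
        more = {"Ramshaw:ungrazed": (3, 200.0), "BigWhitney:ungrazed": (4, 300.0)}
        _, s1 = build_study(SimulationParams(seed=6), base, years=[2010])
        _, s2 = build_study(SimulationParams(seed=6), more, years=[2010])
        ram2 = {s.probe_id: s for s in s2}
        for s in s1:
            pd.testing.assert_frame_equal(s.records, ram2[s.probe_id].records)


class TestWillows:
    def test_exact_counts_match_survey(self):
        survey = simulate_willows(seed=1)
        counts = survey.records.groupby("reach").size()
        assert counts["Mulkey:ungrazed"] == 980
        assert counts["Mulkey:grazed"] == 75

    def test_poisson_density_mean(self):
        """density 0.01/m over 100 m -> mean count about 1 over many seeds."""
        counts = [
            len(simulate_willows({"R:g": 100.0}, density=0.01,
                                 height_mean_sd={"R:g": (50.0, 10.0)}, seed=s).records)
            for s in range(1000)
        ]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_zero_height_sd_gives_constant_heights(self):
        survey = simulate_willows(
            {"R:g": 50.0}, counts={"R:g": 20}, height_mean_sd={"R:g": (40.0, 0.0)}, seed=2
        )
        assert (survey.records["height_cm"] == 40.0).all()

    def test_rejects_nonpositive_length_and_density(self):
        with pytest.raises(ValueError):
            simulate_willows({"R:g": -5.0}, counts={"R:g": 3})
        with pytest.raises(ValueError):
            simulate_willows({"R:g": 50.0}, density=0.0, height_mean_sd={"R:g": (40, 5)})


class TestOutOfWater:
    def test_empty_day_list_is_identity(self, quiet_params):
        s = simulate_series(make_meta(), quiet_params, [25], 2010)
        assert inject_out_of_water(s, [], seed=0) is s

    def test_injected_day_swings_like_air(self, quiet_params):
        """The injected diel range exceeds twice the clean maximum range."""
        s = simulate_series(make_meta(), quiet_params, [25, 26], 2010)
        clean_range = (
            s.records.groupby(s.records["timestamp"].dt.date)["temp_c"].agg(np.ptp).max()
        )
        day = s.records["timestamp"].dt.date.iloc[0]
        out = inject_out_of_water(s, [day], seed=1)
        injected = out.records[out.records["timestamp"].dt.date == day]["temp_c"]
        assert injected.max() - injected.min() > 2 * clean_range
        assert out.flags[day] == frozenset({"out_of_water"})

    def test_qc_removes_exactly_the_injected_probe_days(self):
        """15 injected probe-days across the study -> QC removes exactly 15."""
        probes, series = build_study(
            SimulationParams(seed=8), {"Mulkey:grazed": (5, 400.0)}, years=[2010]
        )
        rng = np.random.default_rng(0)
        n_injected = 0
        cleaned = []
        for i, s in enumerate(series):
            days = sorted(set(s.records["timestamp"].dt.date))
            chosen = list(rng.choice(days, size=3, replace=False))
            n_injected += len(chosen)
            cleaned.append(drop_out_of_water_days(inject_out_of_water(s, chosen, seed=i)))
        assert n_injected == 15
        removed = sum(
            len(set(s.records["timestamp"].dt.date)) - len(set(c.records["timestamp"].dt.date))
            for s, c in zip(series, cleaned)
        )
        assert removed == 15

    def test_rejects_days_outside_span(self, quiet_params):
        import datetime

        s = simulate_series(make_meta(), quiet_params, [25], 2010)
        with pytest.raises(ValueError):
            inject_out_of_water(s, [datetime.date(2010, 1, 1)], seed=0)
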