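"""Grazing analyses: vegetation contrasts, willow surveys, gradients, and
mixed-model group comparisons."""

import numpy as np
import pandas as pd
import pytest

from meadowtherm.compare import (
    aggregate_metric,
    binarize_solar,
    compare_groups_lmm,
    gradient_regression,
    shade_logistic,
    vegetation_type_test,
    willow_heights,
    willow_spacing,
)
from meadowtherm.types import WillowSurvey


class TestVegetationTypeTest:
    def test_identical_rows_give_zero(self):
        chi2, df, p = vegetation_type_test([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == 1.0

    def test_hand_computed_2x2(self):
        """[[20,5],[5,20]]: every cell's expectation is 12.5, so
        chi2 = 4 * 7.5^2 / 12.5 = 18."""
        chi2, df, p = vegetation_type_test([[20, 5], [5, 20]])
        assert df == 1
        assert chi2 == pytest.approx(4 * 7.5**2 / 12.5)

    def test_four_class_df(self):
        chi2, df, _ = vegetation_type_test([[3, 6, 5, 3], [10, 4, 2, 1]])
        assert df == 3

    def test_zero_expected_cell_is_error(self):
        with pytest.raises(ValueError, match="merge"):
            vegetation_type_test([[5, 0], [3, 0]])

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            vegetation_type_test([[1, 2, 3]])
        with pytest.raises(ValueError):
            vegetation_type_test([[1.5, 2], [3, 4]])


def _survey(positions_by_reach, heights_by_reach, lengths):
    rows = []
    for reach, pos in positions_by_reach.items():
        treatment = "ungrazed" if "ungrazed" in reach else "grazed"
        for p, h in zip(pos, heights_by_reach[reach]):
            rows.append((reach, treatment, float(p), float(h)))
    return WillowSurvey(
        pd.DataFrame(rows, columns=["reach", "treatment", "position_m", "height_cm"]),
        lengths,
    )


class TestWillowSurveyStats:
    def test_simple_spacing(self):
        s = _survey(
            {"A:grazed": [0, 5, 10], "B:ungrazed": [0, 2, 4, 6]},
            {"A:grazed": [40] * 3, "B:ungrazed": [90] * 4},
            {"A:grazed": 10.0, "B:ungrazed": 6.0},
        )
        out = willow_spacing(s)
        assert out["per_reach"]["A:grazed"]["mean_spacing_m"] == 5.0
        assert out["per_reach"]["B:ungrazed"]["mean_spacing_m"] == 2.0

    def test_survey_count_ratio_matches_field_census(self):
        """Default stem counts: 980 inside vs 75 outside, a 13x ratio."""
        from meadowtherm.synthetic import simulate_willows

        out = willow_spacing(simulate_willows(seed=0))
        n_in = out["per_reach"]["Mulkey:ungrazed"]["count"]
        n_out = out["per_reach"]["Mulkey:grazed"]["count"]
        assert (n_in, n_out) == (980, 75)
        assert round(n_in / n_out) == 13

    def test_uniform_positions_spacing_expectation(self):
        """n uniform points on [0, L]: mean consecutive gap ~ L/(n+1)."""
        rng = np.random.default_rng(3)
        L, n = 1000.0, 49
        means = []
        for _ in range(300):
            pos = np.sort(rng.uniform(0, L, n))
            means.append(np.diff(pos).mean())
        se = np.std(means) / np.sqrt(len(means))
        # mean gap of interior spacings: (range of n points)/(n-1); its
        # expectation is L*(n-1)/(n+1)/(n-1) = L/(n+1)
        assert np.mean(means) == pytest.approx(L / (n + 1), abs=3 * se)

    def test_equal_heights_null_comparison(self):
        rng = np.random.default_rng(4)
        s = _survey(
            {"A:grazed": np.sort(rng.uniform(0, 900, 40)),
             "B:ungrazed": np.sort(rng.uniform(0, 1200, 40))},
            {"A:grazed": [50.0] * 40, "B:ungrazed": [50.0] * 40},
            {"A:grazed": 900.0, "B:ungrazed": 1200.0},
        )
        out = willow_heights(s)
        assert out["per_reach"]["A:grazed"]["mean_cm"] == 50.0
        assert out["comparison"].coefficient == pytest.approx(0.0, abs=1e-9)
        assert out["comparison"].F == pytest.approx(0.0, abs=1e-9)

    def test_height_f_test_location_invariant(self):
        rng = np.random.default_rng(5)
        pos = {"A:grazed": np.sort(rng.uniform(0, 900, 60)),
               "B:ungrazed": np.sort(rng.uniform(0, 1200, 60))}
        h1 = {"A:grazed": rng.normal(43, 15, 60), "B:ungrazed": rng.normal(92, 25, 60)}
        h2 = {k: v + 100.0 for k, v in h1.items()}
        lengths = {"A:grazed": 900.0, "B:ungrazed": 1200.0}
        f1 = willow_heights(_survey(pos, h1, lengths))["comparison"].F
        f2 = willow_heights(_survey(pos, h2, lengths))["comparison"].F
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_generated_heights_recover_twofold_ratio(self):
        """Defaults draw heights at 92 vs 43 cm: ratio about 2.1."""
        from meadowtherm.synthetic import simulate_willows

        out = willow_heights(simulate_willows(seed=1))
        ratio = (
            out["per_reach"]["Mulkey:ungrazed"]["mean_cm"]
            / out["per_reach"]["Mulkey:grazed"]["mean_cm"]
        )
        assert ratio == pytest.approx(2.1, abs=0.25)
        assert out["comparison"].p_value < 0.001


class TestBinarizeSolar:
    @pytest.mark.parametrize("value,expected", [(98.0, 1), (97.9, 0), (100.0, 1), (0.0, 0)])
    def test_threshold(self, value, expected):
        assert binarize_solar(value) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            binarize_solar(101.0)


class TestShadeLogistic:
    def test_identical_proportions_null(self):
        sunny = [1, 0, 1, 0] * 10
        tr = ["grazed"] * 20 + ["ungrazed"] * 20
        out = shade_logistic(sunny, tr)
        assert out["z"] == pytest.approx(0.0, abs=1e-6)
        assert out["proportions"] == {"grazed": 0.5, "ungrazed": 0.5}

    def test_complete_separation_flagged_with_fisher_fallback(self):
        sunny = [1] * 20 + [1] * 10 + [0] * 10
        tr = ["grazed"] * 20 + ["ungrazed"] * 20
        out = shade_logistic(sunny, tr)
        assert out["separation"]
        assert 0.0 <= out["p_value"] <= 1.0

    def test_clear_difference_detected(self):
        rng = np.random.default_rng(6)
        sunny = list((rng.random(200) < 0.954).astype(int)) + list(
            (rng.random(200) < 0.70).astype(int)
        )
        tr = ["grazed"] * 200 + ["ungrazed"] * 200
        out = shade_logistic(sunny, tr)
        assert not out["separation"]
        assert out["p_value"] < 0.01


def _season_table(distances, slope_per_100m, intercept=20.0, noise=None, reach="Mulkey:grazed"):
    mwmax = intercept + slope_per_100m * np.asarray(distances) / 100.0
    if noise is not None:
        mwmax = mwmax + noise
    probes = pd.DataFrame(
        {
            "probe_id": [f"P{i:02d}" for i in range(len(distances))],
            "reach": reach,
            "distance_m": distances,
            "lat": 36.4 - np.asarray(distances) / 111_320.0,
            "lon": -118.2,
        }
    )
    season = pd.DataFrame(
        {"probe_id": probes["probe_id"], "MWavgT": mwmax - 3.0, "MWmaxT": mwmax}
    )
    return season, probes


class TestGradientRegression:
    def test_exact_line_recovered(self):
        season, probes = _season_table(np.linspace(0, 900, 17), 0.41)
        fit = gradient_regression(season, probes)["Mulkey:grazed"]
        assert fit.slope_per_100m == pytest.approx(0.41, abs=1e-10)
        assert fit.se_per_100m == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 15

    def test_flat_reach_is_null(self):
        season, probes = _season_table(np.linspace(0, 1500, 30), 0.0, reach="Ramshaw:ungrazed")
        fit = gradient_regression(season, probes)["Ramshaw:ungrazed"]
        assert fit.slope_per_100m == pytest.approx(0.0, abs=1e-10)

    def test_distance_rescaling_equivariance(self):
        """Rescaling recorded distances x10 rescales the per-100m slope by
        1/10 while t and p are unchanged."""
        rng = np.random.default_rng(7)
        noise = rng.normal(0, 0.5, 17)
        season, probes = _season_table(np.linspace(0, 900, 17), 0.41, noise=noise)
        fit = gradient_regression(season, probes)["Mulkey:grazed"]
        probes10 = probes.assign(distance_m=probes["distance_m"] * 10)
        fit10 = gradient_regression(season, probes10)["Mulkey:grazed"]
        assert fit10.slope_per_100m == pytest.approx(fit.slope_per_100m / 10)
        assert fit10.t == pytest.approx(fit.t)
        assert fit10.p_value == pytest.approx(fit.p_value)

    def test_too_few_probes_rejected(self):
        season, probes = _season_table([0.0, 100.0], 0.4)
        with pytest.raises(ValueError, match=">= 3"):
            gradient_regression(season, probes)


def _weekly_table(values_by_probe, reaches, start="2010-06-14", n_days=56):
    dates = pd.date_range(start, periods=n_days, freq="D").date
    rows = []
    for pid, v in values_by_probe.items():
        for d, val in zip(dates, np.broadcast_to(v, n_days)):
            rows.append((pid, d, val - 2.0, val, val + 3.0))
    weekly = pd.DataFrame(rows, columns=["probe_id", "date", "WminT", "WavgT", "WmaxT"])
    weekly["n_days"] = 7
    probes = pd.DataFrame({"probe_id": list(values_by_probe), "reach": reaches})
    return weekly, probes


class TestAggregateMetric:
    def test_single_week_identity(self):
        weekly, probes = _weekly_table({"P1": 10.0}, ["A"], n_days=7)
        agg = aggregate_metric(weekly, probes, "week", "per_probe")
        assert len(agg) == 1
        assert agg["WavgT"].iloc[0] == 10.0

    def test_per_reach_pools_probes(self):
        weekly, probes = _weekly_table({"P1": 10.0, "P2": 14.0}, ["A", "A"])
        agg = aggregate_metric(weekly, probes, "month", "per_reach")
        assert (agg["WavgT"] == 12.0).all()

    def test_scales_agree_on_noise_free_data(self):
        """Week / month / year aggregation give identical group differences
        when the data are constant per probe."""
        weekly, probes = _weekly_table({"P1": 10.0, "P2": 13.0}, ["A", "B"])
        diffs = {}
        for scale in ("week", "month", "year"):
            agg = aggregate_metric(weekly, probes, scale, "per_reach")
            piv = agg.pivot(index="unit", columns="reach", values="WavgT")
            diffs[scale] = float((piv["B"] - piv["A"]).mean())
        assert max(diffs.values()) - min(diffs.values()) < 0.1


class TestCompareGroupsLMM:
    def test_exact_offset_detected(self):
        """Two reaches differing by exactly 2 C with no noise: the contrast
        is 2.00 and p collapses to zero."""
        rng = np.random.default_rng(8)
        shared = rng.normal(12, 1, 56)  # same day pattern in both groups
        weekly, probes = _weekly_table(
            {"P1": shared, "P2": shared + 2.0}, ["A", "B"]
        )
        agg = aggregate_metric(weekly, probes, "month", "per_reach")
        res = [r for r in compare_groups_lmm(agg, "month", "per_reach") if r.metric == "WavgT"]
        (contrast,) = res
        assert contrast.difference == pytest.approx(-2.0, abs=1e-9)  # A - B
        assert contrast.p_value < 1e-9

    def test_contrast_orientation_and_antisymmetry(self):
        weekly, probes = _weekly_table({"P1": 10.0, "P2": 14.0, "P3": 11.0}, ["A", "B", "C"])
        rng = np.random.default_rng(9)
        weekly["WavgT"] += rng.normal(0, 0.1, len(weekly))
        agg = aggregate_metric(weekly, probes, "month", "per_reach")
        res = {(r.group_a, r.group_b): r for r in compare_groups_lmm(agg, "month", "per_reach")
               if r.metric == "WavgT"}
        assert res[("A", "B")].difference == pytest.approx(-4.0, abs=0.2)
        assert res[("A", "C")].difference == pytest.approx(-1.0, abs=0.2)
        assert res[("B", "C")].difference == pytest.approx(3.0, abs=0.2)

    def test_requires_two_groups_and_two_units(self):
        weekly, probes = _weekly_table({"P1": 10.0}, ["A"], n_days=7)
        agg = aggregate_metric(weekly, probes, "week", "per_reach")
        with pytest.raises(ValueError):
            compare_groups_lmm(agg, "week", "per_reach")
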