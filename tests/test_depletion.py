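"""Depletion meta-analysis: impact model, PD model, aggregation, propagation."""

import math

import numpy as np
import pandas as pd
import pytest

from benthicstatus import depletion, synth


@pytest.fixture(scope="module")
def study_spec():
    return synth.SynthStudySpec(seed=42)


@pytest.fixture(scope="module")
def impact_records(study_spec):
    return synth.gen_impact_experiments(study_spec)


@pytest.fixture(scope="module")
def impact_fit(impact_records):
    return depletion.fit_impact_model(impact_records, seed=7)


@pytest.fixture(scope="module")
def pd_records(study_spec):
    return synth.gen_pd_records(study_spec)


@pytest.fixture(scope="module")
def pd_fit(pd_records):
    return depletion.fit_pd_model(pd_records)


@pytest.fixture(scope="module")
def freqs(impact_records):
    return impact_records.groupby(["gear", "habitat"]).size().unstack(fill_value=0)


class TestFitImpactModel:
    def test_recovers_true_intercepts(self, study_spec, impact_fit):
        """Fitted i lies within its 95% CI of the generating truth."""
        for gear, i_true in study_spec.true_i.items():
            row = impact_fit.loc[gear]
            assert abs(row["i"] - i_true) < 1.96 * row["i_se"] * 1.5

    def test_backtransform_brackets_point(self, impact_fit):
        for _, row in impact_fit.iterrows():
            assert row["d_lcl"] <= row["d"] <= row["d_ucl"]
            assert row["d"] == pytest.approx(1 - math.exp(row["i"])) or row["d"] == 0.0

    def test_zero_response_gives_zero_depletion(self):
        rows = []
        for s in range(4):
            for t in (0.0, 10.0, 100.0):
                rows.append(
                    dict(study_id=f"s{s}", gear="otter_trawl", habitat="sand",
                         metric="biomass", fauna="epifauna", days_after=t, lnRR=0.0)
                )
        fit = depletion.fit_impact_model(pd.DataFrame(rows), seed=1)
        assert fit.loc["otter_trawl", "i"] == pytest.approx(0.0, abs=1e-8)
        assert fit.loc["otter_trawl", "d"] == pytest.approx(0.0, abs=1e-8)

    def test_exact_backtransform(self):
        assert 1 - math.exp(-0.3) == pytest.approx(0.2592, abs=1e-4)

    def test_insufficient_studies_rejected(self):
        rows = [
            dict(study_id="only", gear="beam_trawl", habitat="sand",
                 metric="biomass", fauna="epifauna", days_after=0.0, lnRR=-0.2)
        ]
        with pytest.raises(ValueError, match="singular|studies"):
            depletion.fit_impact_model(pd.DataFrame(rows))

    def test_no_time_zero_rejected(self):
        rows = [
            dict(study_id=f"s{s}", gear="beam_trawl", habitat="sand",
                 metric="biomass", fauna="epifauna", days_after=400.0, lnRR=-0.2)
            for s in range(3)
        ]
        with pytest.raises(ValueError, match="time 0"):
            depletion.fit_impact_model(pd.DataFrame(rows))


class TestPDModel:
    def test_recovers_component_means(self, study_spec, pd_fit):
        """Back-transformed component means track the generating depths."""
        tbl = pd_fit.table
        for (gear, comp), true_pd in study_spec.true_component_pd.items():
            sand = tbl[(tbl.gear == gear) & (tbl.component == comp) & (tbl.habitat == "sand")]
            fitted = sand["pd_cm"].iloc[0]
            # lognormal noise sd 0.25, ~18 records per component: generous 3 SE band
            assert fitted == pytest.approx(true_pd, rel=0.35)

    def test_habitat_contrast_recovered(self):
        """A true 2x mud/sand depth ratio appears as a log-2 offset."""
        spec = synth.SynthStudySpec(
            seed=17,
            habitat_pd_multiplier={"gravel": 1.0, "sand": 1.0, "mud": 2.0},
            n_pd_records_per_cell=12,
        )
        fit = depletion.fit_pd_model(synth.gen_pd_records(spec))
        tbl = fit.table
        sub = tbl[(tbl.gear == "otter_trawl") & (tbl.component == "doors")]
        log_mud = sub[sub.habitat == "mud"]["log_mean"].iloc[0]
        log_sand = sub[sub.habitat == "sand"]["log_mean"].iloc[0]
        # contrast SE ~ 0.25*sqrt(2/72) ~ 0.042; 0.13 is a ~3 SE band
        assert log_mud - log_sand == pytest.approx(math.log(2.0), abs=0.13)

    def test_single_record_flagged(self):
        rec = pd.DataFrame(
            [dict(study_id="s1", gear="beam_trawl", component="whole_gear",
                  habitat="sand", pd_cm=2.0, width_prop=1.0)]
        )
        fit = depletion.fit_pd_model(rec)
        row = fit.table.iloc[0]
        assert row["pd_cm"] == pytest.approx(2.0)
        assert math.isnan(row["log_se"])  # SE undefined with no residual df

    def test_nonpositive_depth_rejected(self):
        rec = pd.DataFrame(
            [dict(study_id="s1", gear="beam_trawl", component="whole_gear",
                  habitat="sand", pd_cm=0.0, width_prop=1.0)]
        )
        with pytest.raises(ValueError):
            depletion.fit_pd_model(rec)


class TestAggregation:
    def test_weighted_sum(self):
        comp = pd.DataFrame(
            [
                dict(gear="otter_trawl", component="doors", habitat="sand", pd_cm=15.0),
                dict(gear="otter_trawl", component="sweeps", habitat="sand", pd_cm=1.0),
                dict(gear="otter_trawl", component="ground_gear", habitat="sand", pd_cm=3.0),
            ]
        )
        w = {("otter_trawl", "doors"): 0.05, ("otter_trawl", "sweeps"): 0.70,
             ("otter_trawl", "ground_gear"): 0.25}
        out = depletion.aggregate_whole_gear_pd(comp, w)
        assert out.loc[("otter_trawl", "sand"), "pd_cm"] == pytest.approx(2.20)

    def test_single_full_width_component(self):
        comp = pd.DataFrame(
            [dict(gear="beam_trawl", component="whole_gear", habitat="sand", pd_cm=4.1)]
        )
        out = depletion.aggregate_whole_gear_pd(comp, {("beam_trawl", "whole_gear"): 1.0})
        assert out.loc[("beam_trawl", "sand"), "pd_cm"] == pytest.approx(4.1)

    def test_width_overflow_rejected(self):
        comp = pd.DataFrame(
            [dict(gear="beam_trawl", component="whole_gear", habitat="sand", pd_cm=4.1)]
        )
        with pytest.raises(ValueError, match="width"):
            depletion.aggregate_whole_gear_pd(comp, {("beam_trawl", "whole_gear"): 1.2})

    def test_bounded_by_components(self, pd_fit):
        out = depletion.aggregate_whole_gear_pd(pd_fit.table, pd_fit.width_props)
        for (gear, habitat), row in out.iterrows():
            sub = pd_fit.table[(pd_fit.table.gear == gear) & (pd_fit.table.habitat == habitat)]
            total_w = sum(pd_fit.width_props[(gear, c)] for c in sub["component"])
            assert row["pd_cm"] <= sub["pd_cm"].max() * total_w + 1e-9
            assert row["pd_cm"] >= sub["pd_cm"].min() * total_w - 1e-9


class TestSamplePDUncertainty:
    def test_zero_se_degenerate(self):
        tbl = pd.DataFrame(
            [dict(gear="beam_trawl", component="whole_gear", habitat="sand",
                  log_mean=math.log(3.0), log_se=0.0, pd_cm=3.0)]
        )
        fit = depletion.PDModelFit(tbl, {("beam_trawl", "whole_gear"): 1.0})
        _, summary = depletion.sample_pd_uncertainty(fit, n_samples=500, seed=0)
        row = summary.loc[("beam_trawl", "sand")]
        assert row["pd_se"] == 0.0
        assert row["pd_lcl"] == row["pd_ucl"] == pytest.approx(3.0)

    def test_lognormal_quantiles(self):
        """Single component: sampled quantiles match exp(mu +/- 1.96 sigma)."""
        mu, sigma = math.log(5.0), 0.2
        tbl = pd.DataFrame(
            [dict(gear="beam_trawl", component="whole_gear", habitat="sand",
                  log_mean=mu, log_se=sigma, pd_cm=5.0)]
        )
        fit = depletion.PDModelFit(tbl, {("beam_trawl", "whole_gear"): 1.0})
        _, summary = depletion.sample_pd_uncertainty(fit, n_samples=20000, seed=1)
        row = summary.loc[("beam_trawl", "sand")]
        assert row["pd_lcl"] == pytest.approx(math.exp(mu - 1.96 * sigma), rel=0.02)
        assert row["pd_ucl"] == pytest.approx(math.exp(mu + 1.96 * sigma), rel=0.02)

    def test_two_component_variance_algebra(self):
        """Whole-gear sampling SD matches the weighted lognormal variance sum."""
        mu1, s1, mu2, s2 = math.log(10.0), 0.15, math.log(2.0), 0.3
        w1, w2 = 0.3, 0.7
        tbl = pd.DataFrame(
            [
                dict(gear="otter_trawl", component="doors", habitat="sand",
                     log_mean=mu1, log_se=s1, pd_cm=math.exp(mu1)),
                dict(gear="otter_trawl", component="ground_gear", habitat="sand",
                     log_mean=mu2, log_se=s2, pd_cm=math.exp(mu2)),
            ]
        )
        fit = depletion.PDModelFit(
            tbl, {("otter_trawl", "doors"): w1, ("otter_trawl", "ground_gear"): w2}
        )
        _, summary = depletion.sample_pd_uncertainty(fit, n_samples=40000, seed=2)

        def lognorm_var(mu, s):
            return (math.exp(s**2) - 1) * math.exp(2 * mu + s**2)

        expected_sd = math.sqrt(w1**2 * lognorm_var(mu1, s1) + w2**2 * lognorm_var(mu2, s2))
        assert summary.loc[("otter_trawl", "sand"), "pd_se"] == pytest.approx(
            expected_sd, rel=0.05
        )

    def test_reproducible_under_seed(self, pd_fit):
        s1, t1 = depletion.sample_pd_uncertainty(pd_fit, n_samples=300, seed=9)
        s2, t2 = depletion.sample_pd_uncertainty(pd_fit, n_samples=300, seed=9)
        for key in s1:
            np.testing.assert_array_equal(s1[key], s2[key])
        pd.testing.assert_frame_equal(t1, t2)


class TestWeightedGearMean:
    def test_equal_frequencies(self):
        idx = pd.MultiIndex.from_product(
            [["beam_trawl"], ["gravel", "sand", "mud"]], names=["gear", "habitat"]
        )
        tbl = pd.DataFrame({"pd_cm": [1.0, 2.0, 3.0]}, index=idx)
        freqs = pd.DataFrame({"gravel": [2], "sand": [2], "mud": [2]}, index=["beam_trawl"])
        assert depletion.weighted_gear_mean_pd(tbl, freqs)["beam_trawl"] == pytest.approx(2.0)

    def test_weighted(self):
        idx = pd.MultiIndex.from_product(
            [["beam_trawl"], ["gravel", "sand", "mud"]], names=["gear", "habitat"]
        )
        tbl = pd.DataFrame({"pd_cm": [1.0, 2.0, 3.0]}, index=idx)
        freqs = pd.DataFrame({"gravel": [2], "sand": [1], "mud": [1]}, index=["beam_trawl"])
        assert depletion.weighted_gear_mean_pd(tbl, freqs)["beam_trawl"] == pytest.approx(1.75)

    def test_all_zero_rejected(self):
        idx = pd.MultiIndex.from_product(
            [["beam_trawl"], ["sand"]], names=["gear", "habitat"]
        )
        tbl = pd.DataFrame({"pd_cm": [2.0]}, index=idx)
        freqs = pd.DataFrame({"gravel": [0], "sand": [0], "mud": [0]}, index=["beam_trawl"])
        with pytest.raises(ValueError, match="zero"):
            depletion.weighted_gear_mean_pd(tbl, freqs)


class TestDvsLogPD:
    def test_exact_line(self):
        pd_means = pd.Series({"a": 1.0, "b": math.e, "c": math.e**2, "d": math.e**3})
        d_means = pd.Series({g: 0.05 + 0.07 * i for i, g in enumerate("abcd")})
        reg = depletion.fit_d_vs_logpd(d_means, pd_means)
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.slope == pytest.approx(0.07)
        for g in "abcd":
            assert reg.predict(pd_means[g]) == pytest.approx(d_means[g])

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            depletion.fit_d_vs_logpd(
                pd.Series({"a": 0.1, "b": 0.2}), pd.Series({"a": 1.0, "b": 2.0})
            )

    def test_predictions_in_plausible_range(self, impact_fit, pd_fit, freqs):
        """On study-scale synthetic truth, predicted d for the assessment
        gears stays within the plausible 0.02-0.40 band."""
        whole = depletion.aggregate_whole_gear_pd(pd_fit.table, pd_fit.width_props)
        gear_pd = depletion.weighted_gear_mean_pd(whole, freqs)
        reg = depletion.fit_d_vs_logpd(impact_fit["d"], gear_pd)
        assess = whole.loc[["otter_trawl", "beam_trawl", "towed_dredge"]]
        preds = reg.predict(assess["pd_cm"].to_numpy())
        assert np.all(preds >= 0.02) and np.all(preds <= 0.40)

    def test_monotone_ordering_follows_pd(self, impact_fit, pd_fit, freqs):
        """Predicted depletion increases with penetration depth."""
        whole = depletion.aggregate_whole_gear_pd(pd_fit.table, pd_fit.width_props)
        gear_pd = depletion.weighted_gear_mean_pd(whole, freqs)
        reg = depletion.fit_d_vs_logpd(impact_fit["d"], gear_pd)
        assert reg.slope > 0
        order = gear_pd.sort_values()
        preds = reg.predict(order.to_numpy())
        assert np.all(np.diff(preds) >= 0)


class TestMCPropagation:
    def test_zero_variance_degenerate(self, freqs):
        impact = pd.DataFrame(
            {"i": [-0.1, -0.2, -0.3], "i_se": [0.0, 0.0, 0.0]},
            index=["otter_trawl", "beam_trawl", "towed_dredge"],
        )
        impact.index.name = "gear"
        samples = {}
        for gear, pdv in zip(impact.index, (2.0, 3.0, 5.0)):
            for h in ("gravel", "sand", "mud"):
                samples[(gear, h)] = np.full(500, pdv)
        fr = pd.DataFrame(
            {"gravel": [1, 1, 1], "sand": [1, 1, 1], "mud": [1, 1, 1]},
            index=impact.index,
        )
        out = depletion.mc_propagate_depletion(impact, samples, fr, n_samples=500, seed=3)
        assert (out["d_se"] == 0).all()
        assert (out["d_ucl"] == out["d_lcl"]).all()

    def test_reproducible_and_stable(self, impact_fit, pd_fit, freqs):
        samples, _ = depletion.sample_pd_uncertainty(pd_fit, n_samples=2000, seed=5)
        a = depletion.mc_propagate_depletion(impact_fit, samples, freqs, 2000, seed=6)
        b = depletion.mc_propagate_depletion(impact_fit, samples, freqs, 2000, seed=6)
        pd.testing.assert_frame_equal(a, b)
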