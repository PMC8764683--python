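"""Grid assessment: per-cell status, curves, categories, decomposition, risk."""

import numpy as np
import pandas as pd
import pytest

from benthicstatus import assessment, recovery, synth

from conftest import simple_cells


class TestScaleCoverage:
    @pytest.mark.parametrize(
        "F, cov, expected", [(0.5, 100, 0.5), (0.5, 70, 0.5 * 100 / 70), (0.0, 40, 0.0)]
    )
    def test_values(self, F, cov, expected):
        assert assessment.scale_coverage(F, cov) == pytest.approx(expected)

    @pytest.mark.parametrize("cov", [0.0, -5.0, 120.0])
    def test_domain(self, cov):
        with pytest.raises(ValueError):
            assessment.scale_coverage(1.0, cov)


def _one_cell_inputs(F, d=0.5, sand=100.0, gravel=0.0, mud=0.0, gear="otter_trawl"):
    effort = pd.DataFrame(
        [dict(cell_id="c0", lon=0.0, lat=0.0, area_km2=1.0, gear=gear,
              sar=F, coverage_pct=100.0)]
    )
    sediment = pd.DataFrame(
        [dict(cell_id="c0", gravel_pct=gravel, sand_pct=sand, mud_pct=mud)]
    )
    idx = pd.MultiIndex.from_product(
        [[gear], ["gravel", "sand", "mud"]], names=["gear", "habitat"]
    )
    d_table = pd.DataFrame({"d": [d, d, d]}, index=idx)
    return effort, sediment, d_table


class TestAssessCells:
    def test_zero_effort_grid_is_pristine(self, d_table, slope):
        spec = synth.SynthRegionSpec(n_cells=100, untrawled_fraction=1.0, seed=3)
        cells = assessment.assess_cells(
            synth.gen_effort_grid(spec), synth.gen_sediment_grid(spec), d_table, slope
        )
        assert (cells["rbs_mean"] == 1.0).all()
        assert (cells["rbs_lcl"] == 1.0).all()
        assert assessment.regional_mean(cells)["area_weighted"] == 1.0

    def test_threshold_cell(self):
        """F = 0.07 on a habitat with sensitivity 1/0.35 gives status 0.8."""
        # slope chosen so R = 0.175 everywhere; with d = 0.5, d/R = 1/0.35
        b = -1.0 / (0.175 * np.log(10.0))
        sl = recovery.GradientSlope(b0=b)
        effort, sediment, d_tab = _one_cell_inputs(F=0.07, d=0.5)
        cells = assessment.assess_cells(effort, sediment, d_tab, sl)
        assert cells["rbs_mean"].iloc[0] == pytest.approx(0.8)

    def test_gear_split_additivity(self, slope):
        """Two gears splitting the same total F*d match one gear carrying it."""
        idx = pd.MultiIndex.from_product(
            [["otter_trawl", "beam_trawl"], ["gravel", "sand", "mud"]],
            names=["gear", "habitat"],
        )
        d_tab = pd.DataFrame({"d": [0.2] * 6}, index=idx)
        sediment = pd.DataFrame(
            [dict(cell_id="c0", gravel_pct=20.0, sand_pct=50.0, mud_pct=30.0)]
        )
        split = pd.DataFrame(
            [
                dict(cell_id="c0", area_km2=1.0, gear="otter_trawl", sar=0.6,
                     coverage_pct=100.0),
                dict(cell_id="c0", area_km2=1.0, gear="beam_trawl", sar=0.4,
                     coverage_pct=100.0),
            ]
        )
        single = pd.DataFrame(
            [dict(cell_id="c0", area_km2=1.0, gear="otter_trawl", sar=1.0,
                  coverage_pct=100.0)]
        )
        rbs_split = assessment.assess_cells(split, sediment, d_tab, slope)["rbs_mean"].iloc[0]
        rbs_single = assessment.assess_cells(single, sediment, d_tab, slope)["rbs_mean"].iloc[0]
        assert rbs_split == pytest.approx(rbs_single, abs=1e-12)

    def test_hydraulic_dredge_rejected(self, slope, d_table):
        effort, sediment, _ = _one_cell_inputs(F=1.0, gear="hydraulic_dredge")
        idx = pd.MultiIndex.from_product(
            [["hydraulic_dredge"], ["gravel", "sand", "mud"]], names=["gear", "habitat"]
        )
        d_tab = pd.DataFrame({"d": [0.4] * 3}, index=idx)
        with pytest.raises(ValueError, match="not admitted"):
            assessment.assess_cells(effort, sediment, d_tab, slope)

    def test_unmatched_cells_warn(self, d_table, slope):
        effort, sediment, d_tab = _one_cell_inputs(F=0.5)
        sediment_extra = pd.concat(
            [sediment, pd.DataFrame([dict(cell_id="c9", gravel_pct=0.0,
                                          sand_pct=50.0, mud_pct=50.0)])]
        )
        with pytest.warns(UserWarning, match="only one grid"):
            cells = assessment.assess_cells(effort, sediment_extra, d_tab, slope)
        assert len(cells) == 1

    def test_coverage_scaling_applied(self, slope):
        effort, sediment, d_tab = _one_cell_inputs(F=0.5)
        effort["coverage_pct"] = 50.0
        scaled = assessment.assess_cells(effort, sediment, d_tab, slope)
        unscaled = assessment.assess_cells(
            effort, sediment, d_tab, slope, apply_coverage_scaling=False
        )
        assert scaled["f_total"].iloc[0] == pytest.approx(1.0)
        assert unscaled["f_total"].iloc[0] == pytest.approx(0.5)

    def test_lcl_below_mean(self, assessed_cells):
        assert (assessed_cells["rbs_lcl"] <= assessed_cells["rbs_mean"] + 1e-12).all()

    def test_untrawled_iff_status_one(self, assessed_cells):
        untrawled = assessed_cells["f_total"] == 0
        assert ((assessed_cells["rbs_mean"] == 1.0) == untrawled).all()

    def test_doubling_effort_never_raises_status(self, effort_grid, sediment_grid,
                                                 d_table, slope):
        doubled = effort_grid.copy()
        doubled["sar"] = 2 * doubled["sar"]
        base = assessment.assess_cells(effort_grid, sediment_grid, d_table, slope)
        more = assessment.assess_cells(doubled, sediment_grid, d_table, slope)
        assert (more["rbs_mean"] <= base["rbs_mean"] + 1e-12).all()


class TestRegionalMean:
    def test_equal_area(self):
        cells = simple_cells([1.0, 0.8, 0.6])
        m = assessment.regional_mean(cells)
        assert m["area_weighted"] == pytest.approx(0.8)
        assert m["simple"] == pytest.approx(0.8)

    def test_area_weighted(self):
        cells = simple_cells([1.0, 0.4], areas=[2.0, 1.0])
        assert assessment.regional_mean(cells)["area_weighted"] == pytest.approx(0.8)

    def test_single_cell(self):
        assert assessment.regional_mean(simple_cells([0.37]))["area_weighted"] == 0.37


class TestRbsAreaCurve:
    def test_step_construction(self):
        cells = simple_cells([1.0, 0.5, 0.0])
        curve = assessment.rbs_area_curve(cells)
        np.testing.assert_allclose(curve["cum_area_pct"], [100 / 3, 200 / 3, 100.0])
        np.testing.assert_allclose(curve["rbs_mean"], [1.0, 0.5, 0.0])
        auc = float(np.sum(curve["rbs_mean"] * curve["area_km2"]) / curve["area_km2"].sum())
        assert auc == pytest.approx(0.5)

    def test_flat_when_pristine(self):
        curve = assessment.rbs_area_curve(simple_cells([1.0, 1.0, 1.0]))
        assert (curve["rbs_mean"] == 1.0).all()

    def test_auc_equals_weighted_mean(self, assessed_cells):
        """Area under the ordered curve is the area-weighted regional mean."""
        curve = assessment.rbs_area_curve(assessed_cells)
        auc = float(
            np.sum(curve["rbs_mean"] * curve["area_km2"]) / curve["area_km2"].sum()
        )
        assert auc == pytest.approx(
            assessment.regional_mean(assessed_cells)["area_weighted"], abs=1e-10
        )

    def test_curve_value_lookup(self):
        cells = simple_cells([1.0, 0.5, 0.0])
        curve = assessment.rbs_area_curve(cells)
        assert assessment.curve_value_at(curve, 10.0, "rbs_mean") == 1.0
        assert assessment.curve_value_at(curve, 50.0, "rbs_mean") == 0.5
        assert assessment.curve_value_at(curve, 100.0, "rbs_mean") == 0.0


class TestCategoryBreakdown:
    def test_all_untrawled(self):
        out = assessment.category_breakdown(simple_cells([1.0, 1.0]))
        assert out[out.category == "=1"]["area_pct"].iloc[0] == 100.0
        assert out["area_pct"].sum() == pytest.approx(100.0)

    def test_binning(self):
        out = assessment.category_breakdown(simple_cells([1.0, 0.9, 0.5, 0.0]))
        got = dict(zip(out["category"], out["area_pct"]))
        assert got["=1"] == 25.0
        assert got["[0.8,1)"] == 25.0
        assert got["[0.6,0.8)"] == 0.0
        assert got["[0.4,0.6)"] == 25.0
        assert got["(0,0.4)"] == 0.0
        assert got["=0"] == 25.0

    def test_boundary_in_upper_interval(self):
        out = assessment.category_breakdown(simple_cells([0.8]))
        got = dict(zip(out["category"], out["area_pct"]))
        assert got["[0.8,1)"] == 100.0

    def test_sums_to_100_on_synthetic(self, assessed_cells):
        out = assessment.category_breakdown(assessed_cells)
        assert out["area_pct"].sum() == pytest.approx(100.0, abs=1e-9)


class TestDecomposition:
    def test_single_gear(self):
        cells = simple_cells([0.7])
        out = assessment.habitat_gear_decomposition(cells)
        assert out["gear_reduction"]["otter_trawl"] == pytest.approx(0.3)

    def test_additive_attribution(self):
        cells = simple_cells([0.6])
        cells["term_otter_trawl"] = 0.3
        cells["term_beam_trawl"] = 0.1
        out = assessment.habitat_gear_decomposition(cells)
        assert out["gear_reduction"]["otter_trawl"] == pytest.approx(0.3)
        assert out["gear_reduction"]["beam_trawl"] == pytest.approx(0.1)

    def test_clamped_proportional_rescale(self):
        cells = simple_cells([0.0])
        cells["term_otter_trawl"] = 0.9
        cells["term_beam_trawl"] = 0.6
        out = assessment.habitat_gear_decomposition(cells)
        assert out["gear_reduction"]["otter_trawl"] == pytest.approx(0.6)
        assert out["gear_reduction"]["beam_trawl"] == pytest.approx(0.4)

    def test_reductions_sum_to_mean_deficit(self, assessed_cells):
        out = assessment.habitat_gear_decomposition(assessed_cells)
        total_reduction = sum(out["gear_reduction"].values())
        mean = assessment.regional_mean(assessed_cells)["area_weighted"]
        assert total_reduction == pytest.approx(1.0 - mean, abs=1e-10)


class TestThresholdProbability:
    @staticmethod
    def _curves(mean, lcl, ucl):
        mk = lambda v, col: pd.DataFrame({"cum_area_pct": [100.0], col: [v]})
        return (mk(mean, "rbs_mean"), mk(lcl, "rbs_lcl"), mk(ucl, "rbs_ucl"))

    def test_north_sea_style_band(self):
        """A band just below the threshold gives > 97.5% failure risk."""
        p = assessment.threshold_probability(
            *self._curves(0.719, 0.633, 0.790), rbs_threshold=0.8
        )
        assert p > 0.975

    def test_band_above_threshold(self):
        p = assessment.threshold_probability(
            *self._curves(0.93, 0.88, 0.97), rbs_threshold=0.8
        )
        assert p < 0.025

    def test_mean_at_threshold(self):
        p = assessment.threshold_probability(
            *self._curves(0.8, 0.75, 0.85), rbs_threshold=0.8
        )
        assert p == pytest.approx(0.5)

    def test_degenerate_band_step(self):
        assert assessment.threshold_probability(
            *self._curves(0.7, 0.7, 0.7), rbs_threshold=0.8
        ) == 1.0
        assert assessment.threshold_probability(
            *self._curves(0.9, 0.9, 0.9), rbs_threshold=0.8
        ) == 0.0


def test_regional_summary_structure(assessed_cells):
    summary = assessment.regional_summary(assessed_cells, region_id="synthetic")
    assert summary["region_id"] == "synthetic"
    assert 0 <= summary["mean_rbs"] <= 1
    assert summary["mean_rbs_lcl"] <= summary["mean_rbs"]
    assert sum(c["area_pct"] for c in summary["categories"]) == pytest.approx(100.0)
    assert summary["untrawled_area_pct"] == pytest.approx(
        100.0
        * assessed_cells.loc[assessed_cells.f_total == 0, "area_km2"].sum()
        / assessed_cells["area_km2"].sum()
    )
    assert set(summary["footprint"]) >= {
        "uniform_footprint_km2", "area_pct_F_gt_0.35", "area_pct_F_lt_0.07",
    }
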