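"""Survey-stream selection, stream-km apportionment, observed-vs-expected
chi-square, class percentages, and distance-to-high statistics."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from growrisk import (
    ClassThresholds,
    GridError,
    GridSpec,
    LandscapeConfig,
    PointSet,
    Raster,
    StreamNetwork,
    chisq_survey,
    class_percentages,
    classify_risk,
    classify_survey,
    distance_to_class,
    select_survey_streams,
    simulate,
)
from growrisk.classify import HIGH, LOW, MODERATE
from growrisk.validation import SurveyOutcome


def toy_network(lengths_m, names=None, units=None):
    geoms = [LineString([(0, 1000 * i), (length, 1000 * i)])
             for i, length in enumerate(lengths_m)]
    n = len(lengths_m)
    tab = pd.DataFrame({
        "reach_id": [f"r{i}" for i in range(n)],
        "name": names or [f"s{i}" for i in range(n)],
        "unit": units or ["u0"] * n,
    })
    return StreamNetwork(tab, geoms)


def riskmap_from(vals, grid=None, t=(0.4, 0.7)):
    vals = np.asarray(vals, dtype=float)
    grid = grid or GridSpec(*vals.shape, 90.0)
    return classify_risk(Raster(grid, vals), overrides=ClassThresholds(*t))


class TestSurveySelection:
    def test_single_reach_network(self):
        net = toy_network([5000.0])
        plan = select_survey_streams(net, target_fraction=0.01, seed=0)
        assert len(plan.reaches) == 1
        assert plan.total_selected_km == pytest.approx(5.0)

    def test_target_zero_empty_plan(self):
        net = toy_network([5000.0, 3000.0])
        plan = select_survey_streams(net, target_fraction=0.0, seed=0)
        assert len(plan.reaches) == 0

    def test_quarter_target_on_equal_reaches(self):
        net = toy_network([1000.0] * 10)
        plan = select_survey_streams(net, target_fraction=0.25, seed=1)
        assert len(plan.reaches) >= 3
        assert plan.total_selected_km >= 0.25 * plan.network_km

    def test_same_named_reaches_in_unit_come_along(self):
        net = toy_network([1000.0] * 4, names=["s", "s", "s", "t"],
                          units=["u", "u", "v", "u"])
        plan = select_survey_streams(net, target_fraction=0.01, seed=3)
        ids = set(plan.reaches["reach_id"])
        if {"r0", "r1"} & ids:
            assert not ({"r0"} == ids or {"r1"} == ids)  # r0,r1 travel together

    def test_deterministic_under_seed(self):
        net = toy_network([1000.0] * 10)
        p1 = select_survey_streams(net, 0.3, seed=7)
        p2 = select_survey_streams(net, 0.3, seed=7)
        assert list(p1.reaches["reach_id"]) == list(p2.reaches["reach_id"])

    def test_empty_network_errors(self):
        with pytest.raises(GridError):
            select_survey_streams(StreamNetwork(
                pd.DataFrame(columns=["reach_id", "name", "unit"]), []), 0.01)


class TestClassifySurvey:
    def test_reach_entirely_in_one_class(self):
        rm = riskmap_from(np.full((4, 4), 0.9))  # all high
        line = LineString([(0, 180), (360, 180)])
        plots = PointSet.from_xy([100.0], [180.0])
        out = classify_survey(plots, [line], rm)
        assert out.surveyed_km[HIGH] == pytest.approx(0.36)
        assert out.surveyed_km[LOW] == 0.0
        assert out.plot_classes.tolist() == [HIGH]

    def test_reach_split_between_two_classes(self):
        vals = np.full((4, 4), 0.1)
        vals[:, 2:] = 0.5  # right half moderate
        rm = riskmap_from(vals)
        line = LineString([(0, 180), (360, 180)])
        plots = PointSet.from_xy([300.0], [180.0])
        out = classify_survey(plots, [line], rm)
        assert out.surveyed_km[LOW] == pytest.approx(0.18)
        assert out.surveyed_km[MODERATE] == pytest.approx(0.18)
        assert out.plot_classes.tolist() == [MODERATE]

    def test_off_grid_plot_errors(self):
        rm = riskmap_from(np.full((4, 4), 0.9))
        plots = PointSet.from_xy([-100.0], [180.0])
        with pytest.raises(GridError):
            classify_survey(plots, [LineString([(0, 180), (360, 180)])], rm)


class TestChiSquare:
    def test_hand_computed_statistic(self):
        out = SurveyOutcome(surveyed_km={LOW: 80.0, MODERATE: 10.0, HIGH: 10.0},
                            plot_classes=np.array([HIGH] * 9 + [MODERATE] * 3 + [LOW] * 2))
        res = chisq_survey(out)
        # km (10,10,80) with observed (9,3,2) -> expected (1.4,1.4,11.2)
        expected = np.array([11.2, 1.4, 1.4])
        assert res.expected == pytest.approx(expected)
        stat = ((2 - 11.2) ** 2 / 11.2 + (3 - 1.4) ** 2 / 1.4
                + (9 - 1.4) ** 2 / 1.4)
        assert res.statistic == pytest.approx(stat)
        assert res.statistic == pytest.approx(50.64, abs=0.01)
        assert res.df == 2
        assert res.p_value < 1e-4

    def test_expected_conserves_total(self):
        out = SurveyOutcome(surveyed_km={LOW: 5.0, MODERATE: 2.0, HIGH: 3.0},
                            plot_classes=np.array([0, 1, 2, 2, 2]))
        res = chisq_survey(out)
        assert res.expected.sum() == pytest.approx(res.observed.sum(), abs=1e-9)

    def test_proportional_observations_zero_statistic(self):
        out = SurveyOutcome(surveyed_km={LOW: 10.0, MODERATE: 20.0, HIGH: 70.0},
                            plot_classes=np.array([0] + [1] * 2 + [2] * 7))
        assert chisq_survey(out).statistic == pytest.approx(0.0)

    def test_zero_plots_errors(self):
        out = SurveyOutcome(surveyed_km={LOW: 1.0, MODERATE: 1.0, HIGH: 1.0},
                            plot_classes=np.array([], dtype=int))
        with pytest.raises(GridError):
            chisq_survey(out)

    def test_observed_in_unsurveyed_class_errors(self):
        out = SurveyOutcome(surveyed_km={LOW: 0.0, MODERATE: 1.0, HIGH: 1.0},
                            plot_classes=np.array([LOW]))
        with pytest.raises(GridError):
            chisq_survey(out)


class TestClassPercentages:
    def test_all_points_one_class(self):
        rm = riskmap_from(np.full((4, 4), 0.9))
        pts = PointSet.from_xy([50, 150, 250], [50, 150, 250])
        df = class_percentages(pts, rm).set_index("class")
        assert df.loc["high", "percent"] == 100

    def test_printed_counts_round_to_printed_percents(self):
        # counts (34, 26, 32) in (high, moderate, low) -> (37%, 28%, 35%)
        grid = GridSpec(1, 3, 90.0)
        vals = np.array([[0.9, 0.5, 0.1]])
        rm = riskmap_from(vals, grid=grid)
        xs = [45.0] * 34 + [135.0] * 26 + [225.0] * 32
        pts = PointSet.from_xy(xs, [45.0] * 92, ids=range(92))
        df = class_percentages(pts, rm).set_index("class")
        assert df.loc["high", "percent"] == 37
        assert df.loc["moderate", "percent"] == 28
        assert df.loc["low", "percent"] == 35

    def test_nodata_point_excluded(self):
        vals = np.full((4, 4), 0.9)
        grid = GridSpec(4, 4, 90.0)
        r = Raster(grid, vals)
        r.nodata_mask[0, 0] = True
        rm = classify_risk(r, overrides=ClassThresholds(0.4, 0.7))
        rm.nodata_mask[0, 0] = True
        pts = PointSet.from_xy([45.0, 135.0], [315.0, 315.0])
        df = class_percentages(pts, rm)
        assert df["count"].sum() == 1


class TestDistanceToClass:
    def test_inside_high_is_zero(self):
        rm = riskmap_from(np.full((4, 4), 0.9))
        pts = PointSet.from_xy([100.0], [100.0])
        assert distance_to_class(pts, rm)["distance_m"].iloc[0] == 0.0

    def test_no_high_cells_errors(self):
        rm = riskmap_from(np.full((4, 4), 0.1))
        pts = PointSet.from_xy([100.0], [100.0])
        with pytest.raises(GridError):
            distance_to_class(pts, rm)

    def test_one_cell_away_is_90m(self):
        vals = np.full((4, 4), 0.1)
        vals[0, 0] = 0.9  # single high cell, center (45, 315)
        rm = riskmap_from(vals)
        pts = PointSet.from_xy([135.0], [315.0])  # neighboring cell center
        assert distance_to_class(pts, rm)["distance_m"].iloc[0] == pytest.approx(90.0)


class TestSurveyPower:
    def test_discovered_plots_skew_toward_mod_high(self):
        """Plots planted proportionally to suitability are discovered in
        mod-high classes more than surveyed km alone would predict."""
        wins = 0
        for seed in range(20):
            cfg = LandscapeConfig(grid=GridSpec(60, 60, 90.0), n_presences=60,
                                  n_plots=25, n_streams=5, seed=300 + seed)
            truth = simulate(cfg)
            qs = np.nanquantile(truth.suitability.values[truth.suitability.valid],
                                [0.5, 0.8])
            rm = classify_risk(truth.suitability,
                               overrides=ClassThresholds(*qs))
            out = classify_survey(truth.plots, truth.streams, rm)
            km = out.surveyed_km
            km_share = (km[MODERATE] + km[HIGH]) / max(sum(km.values()), 1e-9)
            plot_share = np.mean(out.plot_classes >= MODERATE)
            wins += plot_share > km_share
        assert wins >= 15
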