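"""Synthetic landscape generator: determinism, field structure, the true
selection surface, biased presence sampling, streams/plots, habitat, and
telemetry."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chisquare

from growrisk import (
    BandResponse,
    GridError,
    GridSpec,
    LandscapeConfig,
    LinearResponse,
    Raster,
    TrueModel,
    define_true_suitability,
    gen_habitat,
    gen_predictors,
    gen_streams_and_plots,
    gen_telemetry,
    sample_presences,
    simulate,
)
from growrisk.synthetic import gaussian_field
from conftest import make_stack


@pytest.fixture(scope="module")
def small_cfg():
    return LandscapeConfig(grid=GridSpec(60, 60, 90.0), n_presences=80,
                           n_plots=20, n_streams=4, seed=11)


def morans_i_lag1(field):
    """Sample lag-1 Moran's I (rook neighbors)."""
    z = field - field.mean()
    num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
    w = z[:, :-1].size + z[:-1, :].size
    return (num / w) / (z**2).mean()


class TestPredictors:
    def test_same_seed_identical(self, small_cfg):
        s1, _ = gen_predictors(small_cfg)
        s2, _ = gen_predictors(small_cfg)
        for name in s1.names:
            assert np.array_equal(s1[name].values, s2[name].values)

    def test_constant_elevation_gives_zero_slope(self, grid10):
        z = np.full((10, 10), 1000.0)
        gy, gx = np.gradient(z, 90.0)
        assert np.allclose(100 * np.hypot(gx, gy), 0.0)

    def test_correlation_length_raises_autocorrelation(self, grid10):
        grid = GridSpec(80, 80, 90.0)
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        rough = gaussian_field(grid, 90.0, rng1)
        smooth = gaussian_field(grid, 900.0, rng2)
        assert morans_i_lag1(smooth) > morans_i_lag1(rough)

    def test_correlation_below_cell_size_rejected(self):
        with pytest.raises(GridError):
            LandscapeConfig(grid=GridSpec(10, 10, 90.0),
                            correlation_m={"elevation": 10.0})


class TestTrueSuitability:
    def test_zero_weights_give_half(self, grid5):
        stack = make_stack(grid5, elevation=np.random.default_rng(0).random((5, 5)))
        model = TrueModel(responses=[], intercept=0.0)
        suit = define_true_suitability(stack, model)
        assert np.allclose(suit.values, 0.5)

    def test_band_center_beats_band_edge(self, grid5):
        vals = np.full((5, 5), 1200.0)
        vals[0, 0] = 800.0  # band edge
        stack = make_stack(grid5, elevation=vals)
        model = TrueModel(
            responses=[BandResponse("elevation", 1200.0, 800.0, weight=2.0)],
            intercept=-1.0,
        )
        suit = define_true_suitability(stack, model)
        assert suit.values[1, 1] > suit.values[0, 0]

    def test_hand_computed_two_cells(self):
        grid = GridSpec(1, 2, 90.0)
        stack = make_stack(grid, elevation=[[1000.0, 1400.0]],
                           canopy=[[60.0, 40.0]])
        model = TrueModel(
            responses=[
                BandResponse("elevation", 1200.0, 800.0, weight=3.0, power=2.0),
                LinearResponse("canopy", weight=0.5, center=50.0, scale=25.0),
            ],
            intercept=-1.0,
        )
        suit = define_true_suitability(stack, model)
        for j, (elev, can) in enumerate([(1000.0, 60.0), (1400.0, 40.0)]):
            band = 3.0 * np.exp(-0.5 * abs((elev - 1200.0) / 400.0) ** 2)
            lin = 0.5 * (can - 50.0) / 25.0
            assert suit.values[0, j] == pytest.approx(expit(band + lin - 1.0))

    def test_missing_variable_errors(self, grid5):
        stack = make_stack(grid5, elevation=np.ones((5, 5)))
        model = TrueModel(responses=[LinearResponse("slope", 1.0)])
        with pytest.raises(GridError):
            define_true_suitability(stack, model)


class TestPresenceSampling:
    def test_single_positive_cell_without_replacement_errors(self, grid5):
        suit = np.zeros((5, 5))
        suit[2, 2] = 1.0
        with pytest.raises(GridError):
            sample_presences(Raster(grid5, suit), n=5, seed=0)

    def test_uniform_suitability_quadrant_gof(self):
        grid = GridSpec(20, 20, 90.0)
        suit = Raster(grid, np.ones((20, 20)))
        ps = sample_presences(suit, n=320, seed=42)
        r, c = grid.point_to_cell(ps.xy[:, 0], ps.xy[:, 1])
        quad = (r >= 10) * 2 + (c >= 10)
        counts = np.bincount(quad, minlength=4)
        assert chisquare(counts).pvalue > 0.01

    def test_bias_shifts_expected_counts(self):
        grid = GridSpec(10, 10, 90.0)
        suit = Raster(grid, np.ones((10, 10)))
        bias_vals = np.ones((10, 10))
        bias_vals[:, :5] = 2.0  # left half doubled
        bias = Raster(grid, bias_vals)
        rng = np.random.default_rng(99)
        left = right = 0
        for _ in range(1000):
            ps = sample_presences(suit, n=20, bias=bias, seed=rng)
            left += (ps.xy[:, 0] < 450.0).sum()
            right += (ps.xy[:, 0] >= 450.0).sum()
        assert left > right

    def test_points_lie_in_positive_cells(self, small_cfg):
        truth = simulate(small_cfg)
        s = truth.suitability.sample(truth.presence_points.xy[:, 0],
                                     truth.presence_points.xy[:, 1])
        assert np.all(s > 0)


class TestStreamsPlotsHabitat:
    def test_zero_plots_requested(self, small_cfg):
        cfg = LandscapeConfig(grid=small_cfg.grid, n_plots=0, n_streams=2, seed=3)
        stack, streams = gen_predictors(cfg)
        suit = Raster(cfg.grid, np.full(cfg.grid.shape, 0.5))
        streams, plots = gen_streams_and_plots(cfg, suit, seed=3, streams=streams)
        assert len(plots) == 0

    def test_plots_within_300m_of_stream(self, small_cfg):
        truth = simulate(small_cfg)
        import shapely
        union = shapely.union_all(truth.streams.geometries)
        pts = shapely.points(truth.plots.xy)
        assert np.all(shapely.distance(union, pts) <= 300.0)

    def test_plot_density_tracks_suitability_terciles(self, small_cfg):
        truth = simulate(small_cfg)
        labels = truth.plots.df["true_class"]
        assert (labels == 2).sum() > (labels == 0).sum()

    def test_habitat_quantile_rule(self, grid10, rng):
        vals = rng.standard_normal((10, 10))
        stack = make_stack(grid10, elevation=vals)
        lo, hi = np.quantile(vals, [0.25, 0.75])
        hab = gen_habitat(stack, {"elevation": (lo, hi)})
        frac = hab.values.mean()
        assert 0.4 <= frac <= 0.6

    def test_habitat_always_true_and_false(self, grid5, rng):
        stack = make_stack(grid5, elevation=rng.random((5, 5)))
        assert gen_habitat(stack, {"elevation": (-1e9, 1e9)}).values.all()
        with pytest.raises(GridError):
            gen_habitat(stack, {"elevation": (1e9, 2e9)})


class TestTelemetry:
    def test_location_counts_and_determinism(self, grid10):
        grid = GridSpec(100, 100, 90.0)
        t1 = gen_telemetry(4, 30, 500.0, grid, seed=8)
        t2 = gen_telemetry(4, 30, 500.0, grid, seed=8)
        assert len(t1) == 4
        for aid in t1:
            assert len(t1[aid]) == 30
            assert np.array_equal(t1[aid].xy, t2[aid].xy)

    def test_dispersion_recovered(self):
        grid = GridSpec(300, 300, 90.0)
        t = gen_telemetry(1, 1000, 900.0, grid, seed=4)
        xy = next(iter(t.values())).xy
        center = xy.mean(axis=0)
        d = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
        # for an isotropic bivariate normal E[d^2] = 2 sigma^2
        sigma_hat = np.sqrt((d**2).mean() / 2)
        assert abs(sigma_hat - 900.0) / 900.0 < 0.15

    def test_invalid_count_rejected(self, grid10):
        with pytest.raises(GridError):
            gen_telemetry(2, 0, 500.0, grid10, seed=0)


class TestFullSimulation:
    def test_deterministic_under_seed(self, small_cfg):
        t1 = simulate(small_cfg)
        t2 = simulate(small_cfg)
        assert np.array_equal(t1.suitability.values, t2.suitability.values)
        assert np.array_equal(t1.presence_points.xy, t2.presence_points.xy)
        assert np.array_equal(t1.plots.xy, t2.plots.xy)
        assert t1.streams.table.equals(t2.streams.table)
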