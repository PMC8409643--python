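"""Synthetic landscapes for exercising the risk-modeling pipeline.

Real cultivation-site localities and the GIS layers behind them are not
public, so the package ships a generator that emulates their statistical
structure: spatially autocorrelated predictor fields, a true selection
surface with band-shaped responses (low-to-mid elevation, moderate slopes),
detection-biased presence sampling, stream networks with planted grow plots,
binary habitat layers, and clustered telemetry. Everything is deterministic
under a fixed seed.

The default preset is a desk-scale stand-in for the study region: a 200 x 200
grid of 90 m cells (18 x 18 km), 500 presences, with the elevation band
centered at 1200 m (width 800 m) and the slope band at 45% (width 30%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import expit
from shapely.geometry import LineString

from .io import (
    GridError,
    GridSpec,
    PointSet,
    PredictorStack,
    Raster,
    StreamNetwork,
    distance_transform,
)

logger = logging.getLogger("growrisk")

# correlation lengths (m) of the smoothed Gaussian fields, per layer role
DEFAULT_CORRELATION_M: dict[str, float] = {
    "elevation": 720.0,
    "canopy_cover": 900.0,
    "greenness_noise": 900.0,
    "stand_age": 1350.0,
    "precipitation": 3600.0,
    "aspect_transformed": 450.0,
    "private_field": 2700.0,
    "disturbance_field": 1800.0,
}


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic landscape generator."""

    grid: GridSpec = field(default_factory=lambda: GridSpec(200, 200, 90.0))
    correlation_m: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATION_M)
    )
    n_presences: int = 500
    n_streams: int = 8
    n_roads: int = 3
    n_plots: int = 40
    bias_strength: float = 1.0
    n_animals: int = 12
    locs_per_animal: int = 40
    telemetry_dispersion: float = 900.0
    seed: int = 42

    def __post_init__(self):
        for role, length in self.correlation_m.items():
            if length < self.grid.cell_size:
                raise GridError(
                    f"correlation length for {role!r} must be >= cell_size"
                )


# ---------------------------------------------------------------------------
# Random fields and predictors
# ---------------------------------------------------------------------------

def gaussian_field(grid: GridSpec, correlation_m: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise, standardized to mean 0 / sd 1.

    The Gaussian kernel sigma is the correlation length in cells, so larger
    values give longer-range spatial autocorrelation.
    """
    sigma = correlation_m / grid.cell_size
    white = rng.standard_normal(grid.shape)
    f = ndi.gaussian_filter(white, sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _monotone_path(grid: GridSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random monotone lattice path crossing the grid left to right."""
    row = int(rng.integers(0, grid.n_rows))
    cells = [(row, 0)]
    for col in range(1, grid.n_cols):
        row = int(np.clip(row + rng.integers(-1, 2), 0, grid.n_rows - 1))
        cells.append((row, col))
    return cells


def _path_linestring(grid: GridSpec, cells: Sequence[tuple[int, int]]) -> LineString:
    rows = np.array([r for r, _ in cells])
    cols = np.array([c for _, c in cells])
    x, y = grid.cell_center(rows, cols)
    return LineString(np.column_stack([x, y]))


def gen_streams(grid: GridSpec, n_streams: int, rng: np.random.Generator,
                reaches_per_stream: int = 3, n_units: int = 4) -> StreamNetwork:
    """Random monotone lattice paths split into named reaches.

    Each stream is split into ``reaches_per_stream`` reaches that share the
    stream name; sub-watershed units are vertical strips of the grid, and a
    reach is labeled by the unit containing its midpoint.
    """
    if n_streams < 1:
        raise GridError("at least one stream is required")
    rows_tab, geoms = [], []
    strip = grid.n_cols / n_units
    for s in range(n_streams):
        cells = _monotone_path(grid, rng)
        name = f"stream_{s:02d}"
        bounds = np.linspace(0, len(cells), reaches_per_stream + 1).astype(int)
        for j in range(reaches_per_stream):
            seg = cells[bounds[j]: bounds[j + 1] + 1]
            if len(seg) < 2:
                continue
            mid_col = seg[len(seg) // 2][1]
            unit = f"HUC_{int(mid_col // strip):02d}"
            rows_tab.append(
                {"reach_id": f"{name}_r{j}", "name": name, "unit": unit}
            )
            geoms.append(_path_linestring(grid, seg))
    return StreamNetwork(pd.DataFrame(rows_tab), geoms)


def gen_predictors(config: LandscapeConfig, rng: np.random.Generator | None = None,
                   streams: StreamNetwork | None = None) -> tuple[PredictorStack, StreamNetwork]:
    """Generate the predictor stack (and the stream network used for the
    distance-to-water layer).

    Slope (percent) is derived from the elevation field by central finite
    differences; distance layers come from generated streams, roads, private
    land, and disturbance masks via the Euclidean distance transform.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = config.grid
    corr = {**DEFAULT_CORRELATION_M, **dict(config.correlation_m)}

    stack = PredictorStack(grid)

    # terrain: elevation and derived percent slope
    z = 1200.0 + 500.0 * gaussian_field(grid, corr["elevation"], rng)
    stack.add("elevation", Raster(grid, z))
    gy, gx = np.gradient(z, grid.cell_size)
    slope = 100.0 * np.hypot(gx, gy)
    stack.add("slope", Raster(grid, slope))

    # vegetation: canopy plus a deliberately collinear greenness layer
    zc = gaussian_field(grid, corr["canopy_cover"], rng)
    canopy = np.clip(55.0 + 22.0 * zc, 0.0, 100.0)
    stack.add("canopy_cover", Raster(grid, canopy))
    zn = gaussian_field(grid, corr["greenness_noise"], rng)
    greenness = 0.5 + 0.2 * (0.85 * zc + np.sqrt(1 - 0.85**2) * zn)
    stack.add("greenness", Raster(grid, greenness))

    stand_age = np.clip(100.0 + 55.0 * gaussian_field(grid, corr["stand_age"], rng), 0.0, 400.0)
    stack.add("stand_age", Raster(grid, stand_age))

    precip = np.clip(180.0 + 60.0 * gaussian_field(grid, corr["precipitation"], rng), 40.0, 350.0)
    stack.add("precipitation", Raster(grid, precip))

    aspect = np.clip(gaussian_field(grid, corr["aspect_transformed"], rng), -2.0, 2.0) / 2.0
    stack.add("aspect_transformed", Raster(grid, aspect))

    # distance-to-feature layers
    if streams is None:
        streams = gen_streams(grid, config.n_streams, rng)
    stream_fg = Raster(grid, np.zeros(grid.shape))
    for geom in streams.geometries:
        coords = np.asarray(geom.coords)
        r, c = grid.point_to_cell(coords[:, 0], coords[:, 1])
        stream_fg.values[np.clip(r, 0, grid.n_rows - 1), np.clip(c, 0, grid.n_cols - 1)] = 1.0
    stack.add("dist_water", distance_transform(stream_fg))

    road_fg = Raster(grid, np.zeros(grid.shape))
    for _ in range(max(config.n_roads, 1)):
        for r, c in _monotone_path(grid, rng):
            road_fg.values[r, c] = 1.0
    stack.add("dist_road", distance_transform(road_fg))

    private = gaussian_field(grid, corr["private_field"], rng)
    private_mask = private < np.quantile(private, 0.20)
    stack.add("dist_private", distance_transform(Raster(grid, private_mask.astype(float))))

    disturb = gaussian_field(grid, corr["disturbance_field"], rng)
    disturb_mask = disturb < np.quantile(disturb, 0.15)
    stack.add("dist_disturbance", distance_transform(Raster(grid, disturb_mask.astype(float))))

    return stack, streams


# ---------------------------------------------------------------------------
# True selection surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandResponse:
    """Band response, highest at ``center`` and decaying away from it:
    ``w * exp(-0.5 * |(x - center)/(width/2)|^power)``.

    ``power = 2`` gives a Gaussian bump; larger powers give a flat-topped
    band with steep shoulders at center +/- width/2 (where the response is
    ``w * exp(-0.5)`` regardless of power).
    """

    variable: str
    center: float
    width: float
    weight: float
    power: float = 2.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        half = self.width / 2.0
        return self.weight * np.exp(-0.5 * np.abs((x - self.center) / half) ** self.power)


@dataclass(frozen=True)
class LinearResponse:
    """Linear response on an explicitly scaled variable: w * (x - center)/scale."""

    variable: str
    weight: float
    center: float = 0.0
    scale: float = 1.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.weight * (x - self.center) / self.scale


@dataclass
class TrueModel:
    """True selection surface: inverse-logit of a weighted sum of responses."""

    responses: list = field(default_factory=list)
    intercept: float = 0.0
    bias_strength: float = 0.0

    @property
    def variables(self) -> list[str]:
        return [r.variable for r in self.responses]


ELEVATION_BAND = (1200.0, 800.0)   # center, width (m)
SLOPE_BAND = (45.0, 30.0)          # center, width (percent slope)


def default_true_model(bias_strength: float = 1.0) -> TrueModel:
    """The preset truth: sharply selective elevation and slope bands plus
    weaker water-proximity and canopy preferences.

    Site selection in this system is strongly selective: published class
    maps put only about a quarter of the extent in moderate-to-high
    likelihood. The preset therefore uses flat-topped bands with a large
    in-band/out-of-band contrast, producing a near-binary suitable region
    covering roughly 25% of the landscape.
    """
    return TrueModel(
        responses=[
            BandResponse("elevation", *ELEVATION_BAND, weight=10.0, power=10.0),
            BandResponse("slope", *SLOPE_BAND, weight=10.0, power=10.0),
            LinearResponse("dist_water", weight=-0.4, center=0.0, scale=2000.0),
            LinearResponse("canopy_cover", weight=0.3, center=50.0, scale=25.0),
        ],
        intercept=-15.0,
        bias_strength=bias_strength,
    )


def define_true_suitability(stack: PredictorStack, model: TrueModel) -> Raster:
    """Cellwise inverse-logit of the weighted response sum; values in [0, 1]."""
    missing = [v for v in model.variables if v not in stack]
    if missing:
        raise GridError(f"true model variables missing from stack: {missing}")
    eta = np.full(stack.grid.shape, model.intercept, dtype=float)
    for resp in model.responses:
        eta += resp(stack[resp.variable].values)
    suit = expit(eta)
    mask = ~stack.combined_valid()
    suit = suit.copy()
    suit[mask] = np.nan
    return Raster(stack.grid, suit, mask)


# ---------------------------------------------------------------------------
# Presence sampling with detection bias
# ---------------------------------------------------------------------------

def make_detection_bias(suitability: Raster, strength: float,
                        rng: np.random.Generator, n_seed_points: int = 150,
                        smooth_cells: float = 5.0) -> Raster:
    """Detection-bias surface emulating enforcement search behavior: a
    smoothed density of previously "found" sites, mixed multiplicatively.

    Returns a raster of ``1 + strength * density`` with density normalized to
    peak 1, so ``strength = 0`` yields a flat (unbiased) surface.
    """
    grid = suitability.grid
    w = np.where(suitability.valid, np.nan_to_num(suitability.values), 0.0).ravel()
    if w.sum() <= 0:
        raise GridError("suitability has no positive cells")
    idx = rng.choice(w.size, size=n_seed_points, replace=True, p=w / w.sum())
    counts = np.bincount(idx, minlength=w.size).reshape(grid.shape).astype(float)
    dens = ndi.gaussian_filter(counts, sigma=smooth_cells)
    if dens.max() > 0:
        dens = dens / dens.max()
    return Raster(grid, 1.0 + strength * dens)


def sample_presences(suitability: Raster, n: int, bias: Raster | None = None,
                     seed=None) -> PointSet:
    """Draw ``n`` presence cells without replacement with probability
    proportional to suitability (times bias, if given), jittered uniformly
    within the cell."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid = suitability.grid
    w = np.where(suitability.valid, np.nan_to_num(suitability.values), 0.0)
    if bias is not None:
        w = w * np.where(bias.valid, bias.values, 0.0)
    flat = w.ravel()
    eligible = np.flatnonzero(flat > 0)
    if n > eligible.size:
        raise GridError(
            f"cannot draw {n} presence cells without replacement from "
            f"{eligible.size} cells with positive weight"
        )
    p = flat[eligible] / flat[eligible].sum()
    chosen = rng.choice(eligible, size=n, replace=False, p=p)
    rows, cols = np.unravel_index(chosen, grid.shape)
    cx, cy = grid.cell_center(rows, cols)
    half = grid.cell_size / 2.0
    x = cx + rng.uniform(-half, half, size=n)
    y = cy + rng.uniform(-half, half, size=n)
    return PointSet.from_xy(x, y, ids=[f"occ{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# Streams, plots, habitat, telemetry
# ---------------------------------------------------------------------------

def gen_streams_and_plots(config: LandscapeConfig, suitability: Raster,
                          seed=None, streams: StreamNetwork | None = None
                          ) -> tuple[StreamNetwork, PointSet]:
    """Stream network plus grow plots planted near streams in proportion to
    suitability; every plot lies within 300 m of a stream."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid = suitability.grid
    if streams is None:
        streams = gen_streams(grid, config.n_streams, rng)
    if config.n_plots == 0:
        return streams, PointSet(pd.DataFrame({"id": [], "x": [], "y": []}))

    fg = Raster(grid, np.zeros(grid.shape))
    for geom in streams.geometries:
        coords = np.asarray(geom.coords)
        r, c = grid.point_to_cell(coords[:, 0], coords[:, 1])
        fg.values[np.clip(r, 0, grid.n_rows - 1), np.clip(c, 0, grid.n_cols - 1)] = 1.0
    dist = distance_transform(fg)
    # cell centers within 200 m keep jittered plots comfortably inside 300 m
    near = (dist.values <= 200.0) & suitability.valid
    w = np.where(near, np.nan_to_num(suitability.values), 0.0).ravel()
    eligible = np.flatnonzero(w > 0)
    n = min(config.n_plots, eligible.size)
    chosen = rng.choice(eligible, size=n, replace=False, p=w[eligible] / w[eligible].sum())
    rows, cols = np.unravel_index(chosen, grid.shape)
    cx, cy = grid.cell_center(rows, cols)
    half = grid.cell_size / 2.0
    x = cx + rng.uniform(-half, half, size=n)
    y = cy + rng.uniform(-half, half, size=n)
    s = suitability.values[rows, cols]
    terc = np.nanquantile(np.where(suitability.valid, suitability.values, np.nan), [1 / 3, 2 / 3])
    labels = np.digitize(s, terc)  # 0 = bottom tercile, 2 = top
    plots = PointSet(pd.DataFrame({
        "id": [f"plot{i}" for i in range(n)],
        "x": x, "y": y,
        "suitability": s,
        "true_class": labels,
    }))
    return streams, plots


def gen_habitat(stack: PredictorStack, rule: Mapping[str, tuple[float, float]]) -> Raster:
    """Binary habitat raster from interval rules on predictor layers.

    ``rule`` maps variable name -> (low, high); a cell is suitable when every
    variable falls inside its closed interval.
    """
    missing = [v for v in rule if v not in stack]
    if missing:
        raise GridError(f"habitat rule variables missing from stack: {missing}")
    grid = stack.grid
    ok = stack.combined_valid()
    suitable = ok.copy()
    for var, (lo, hi) in rule.items():
        v = stack[var].values
        suitable &= (v >= lo) & (v <= hi)
    if not suitable.any():
        raise GridError("habitat rule selects zero cells")
    frac = suitable.sum() / max(ok.sum(), 1)
    logger.info("gen_habitat: %.1f%% of valid cells suitable", 100 * frac)
    return Raster(grid, suitable.astype(float), ~ok)


def gen_telemetry(n_animals: int, locs_per_animal: int, dispersion: float,
                  grid: GridSpec, seed=None) -> dict[str, PointSet]:
    """Clustered telemetry: per animal, a uniform center and isotropic
    bivariate-normal locations (sd = dispersion, m) truncated to the grid."""
    if locs_per_animal < 1:
        raise GridError("locs_per_animal must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    xmin, ymin, xmax, ymax = grid.bounds
    inset = min(3 * dispersion, 0.45 * (xmax - xmin))
    out: dict[str, PointSet] = {}
    eps = 1e-6
    for a in range(n_animals):
        cx = rng.uniform(xmin + inset, xmax - inset)
        cy = rng.uniform(ymin + inset, ymax - inset)
        x = np.clip(cx + dispersion * rng.standard_normal(locs_per_animal), xmin + eps, xmax - eps)
        y = np.clip(cy + dispersion * rng.standard_normal(locs_per_animal), ymin + eps, ymax - eps)
        aid = f"animal_{a:02d}"
        out[aid] = PointSet.from_xy(
            x, y, ids=[f"{aid}_l{i}" for i in range(locs_per_animal)], group=aid
        )
    return out


# ---------------------------------------------------------------------------
# Full synthetic truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Everything the downstream pipeline needs, with the generating truth."""

    stack: PredictorStack
    true_model: TrueModel
    suitability: Raster
    bias: Raster
    presence_points: PointSet
    streams: StreamNetwork
    plots: PointSet
    habitat: Raster
    telemetry: dict[str, PointSet]


def simulate(config: LandscapeConfig, true_model: TrueModel | None = None) -> SyntheticTruth:
    """Generate the full synthetic study system under one seed."""
    rng = np.random.default_rng(config.seed)
    if true_model is None:
        true_model = default_true_model(bias_strength=config.bias_strength)
    stack, streams = gen_predictors(config, rng)
    suitability = define_true_suitability(stack, true_model)
    bias = make_detection_bias(suitability, true_model.bias_strength, rng)
    presences = sample_presences(suitability, config.n_presences, bias=bias, seed=rng)
    streams, plots = gen_streams_and_plots(config, suitability, seed=rng, streams=streams)
    habitat = gen_habitat(
        stack,
        {"elevation": (900.0, 2000.0), "canopy_cover": (45.0, 100.0)},
    )
    telemetry = gen_telemetry(
        config.n_animals, config.locs_per_animal, config.telemetry_dispersion,
        config.grid, seed=rng,
    )
    return SyntheticTruth(
        stack=stack,
        true_model=true_model,
        suitability=suitability,
        bias=bias,
        presence_points=presences,
        streams=streams,
        plots=plots,
        habitat=habitat,
        telemetry=telemetry,
    )
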