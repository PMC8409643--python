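"""Ground-truth survey design and validation statistics.

The survey design walks randomly chosen stream reaches until a target
fraction (1% by default) of total stream length is covered; discovered plots
are compared with expectation in an observed-vs-expected chi-square where
the expected count per risk class is the class's share of *surveyed stream
kilometers* times the total number of plots found. Independent locality sets
are summarized as per-class percentages, and for sites outside the high
class, as distances to the nearest high-likelihood cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from scipy.stats import chi2
from shapely.geometry import box

from .classify import CLASS_NAMES, HIGH, LOW, MODERATE, RiskMap
from .io import GridError, PointSet, StreamNetwork

logger = logging.getLogger("growrisk")


@dataclass
class SurveyPlan:
    reaches: pd.DataFrame  # reach_id, name, unit, length_km
    total_selected_km: float
    target_fraction: float
    network_km: float


@dataclass
class SurveyOutcome:
    surveyed_km: dict[int, float]      # class -> stream km surveyed
    plot_classes: np.ndarray           # per discovered plot, class label


@dataclass
class ChiSquareResult:
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float


def select_survey_streams(network: StreamNetwork, target_fraction: float = 0.01,
                          seed=None) -> SurveyPlan:
    """Accumulate randomly drawn reaches (plus all same-named reaches in the
    drawn reach's sub-watershed unit) until the selected length reaches the
    target fraction of total network length."""
    if len(network) == 0:
        raise GridError("select_survey_streams: empty network")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tab = network.table.reset_index(drop=True)
    total_km = float(tab["length_km"].sum())
    target_km = target_fraction * total_km
    selected = np.zeros(len(tab), dtype=bool)
    selected_km = 0.0
    while selected_km < target_km and not selected.all():
        pool = np.flatnonzero(~selected)
        pick = int(rng.choice(pool))
        name, unit = tab.loc[pick, "name"], tab.loc[pick, "unit"]
        group = (~selected) & (tab["name"] == name).to_numpy() & (tab["unit"] == unit).to_numpy()
        selected |= group
        selected_km = float(tab.loc[selected, "length_km"].sum())
    plan = SurveyPlan(
        reaches=tab[selected].reset_index(drop=True),
        total_selected_km=selected_km,
        target_fraction=target_fraction,
        network_km=total_km,
    )
    logger.info("select_survey_streams: %d reaches, %.1f of %.1f km (target %.1f)",
                len(plan.reaches), selected_km, total_km, target_km)
    return plan


def _reach_km_by_class(geom, riskmap: RiskMap) -> dict[int, float]:
    """Apportion a reach's length to risk classes by line/cell intersection."""
    grid = riskmap.grid
    out = {LOW: 0.0, MODERATE: 0.0, HIGH: 0.0}
    xmin, ymin, xmax, ymax = geom.bounds
    r0, c0 = grid.point_to_cell(xmin, ymax)
    r1, c1 = grid.point_to_cell(xmax, ymin)
    r0, r1 = max(int(r0), 0), min(int(r1), grid.n_rows - 1)
    c0, c1 = max(int(c0), 0), min(int(c1), grid.n_cols - 1)
    for rr in range(r0, r1 + 1):
        for cc in range(c0, c1 + 1):
            x0 = grid.origin_x + cc * grid.cell_size
            y1 = grid.origin_y - rr * grid.cell_size
            cell = box(x0, y1 - grid.cell_size, x0 + grid.cell_size, y1)
            seg = geom.intersection(cell)
            if seg.is_empty:
                continue
            if riskmap.nodata_mask[rr, cc]:
                continue
            out[int(riskmap.classes[rr, cc])] += seg.length / 1000.0
    return out


def classify_survey(plots: PointSet, surveyed: StreamNetwork | list,
                    riskmap: RiskMap) -> SurveyOutcome:
    """Surveyed stream km per risk class (line/cell intersection lengths)
    and a class label for every discovered plot."""
    geoms = surveyed.geometries if isinstance(surveyed, StreamNetwork) else list(surveyed)
    km = {LOW: 0.0, MODERATE: 0.0, HIGH: 0.0}
    for geom in geoms:
        part = _reach_km_by_class(geom, riskmap)
        for k in km:
            km[k] += part[k]
    xy = plots.xy
    on = riskmap.grid.contains(xy[:, 0], xy[:, 1])
    if not on.all():
        raise GridError("classify_survey: plot located off the risk map grid")
    r, c = riskmap.grid.point_to_cell(xy[:, 0], xy[:, 1])
    if riskmap.nodata_mask[r, c].any():
        raise GridError("classify_survey: plot located on a nodata cell")
    return SurveyOutcome(surveyed_km=km, plot_classes=riskmap.classes[r, c].astype(int))


def chisq_survey(outcome: SurveyOutcome) -> ChiSquareResult:
    """Observed-vs-expected chi-square with stream-km-weighted expectations.

    expected_c = (km_c / total km) * N plots; df = (classes with surveyed
    km) - 1; the p-value is the chi-square upper tail.
    """
    classes = sorted(outcome.surveyed_km)
    km = np.array([outcome.surveyed_km[c] for c in classes], dtype=float)
    obs = np.array([(outcome.plot_classes == c).sum() for c in classes], dtype=float)
    n = obs.sum()
    if n < 1:
        raise GridError("chisq_survey: zero plots discovered")
    if np.any((obs > 0) & (km <= 0)):
        raise GridError("chisq_survey: plots observed in a class with zero surveyed km")
    has_km = km > 0
    km, obs = km[has_km], obs[has_km]
    expected = km / km.sum() * n
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = int(has_km.sum()) - 1
    p = float(chi2.sf(stat, df)) if df > 0 else float("nan")
    return ChiSquareResult(observed=obs, expected=expected, statistic=stat,
                           df=df, p_value=p)


def class_percentages(points: PointSet, riskmap: RiskMap) -> pd.DataFrame:
    """Per-class counts and percentages of independent localities; off-grid
    or nodata points are excluded with a logged count."""
    xy = points.xy
    on = riskmap.grid.contains(xy[:, 0], xy[:, 1])
    r, c = riskmap.grid.point_to_cell(xy[:, 0], xy[:, 1])
    usable = on.copy()
    usable[on] &= ~riskmap.nodata_mask[r[on], c[on]]
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("class_percentages: excluded %d off-grid/nodata point(s)", n_excluded)
    if not usable.any():
        raise GridError("class_percentages: no usable points on the risk map")
    labels = riskmap.classes[r[usable], c[usable]]
    rows = []
    total = labels.size
    for cls in (LOW, MODERATE, HIGH):
        count = int((labels == cls).sum())
        frac = count / total
        rows.append({"class": CLASS_NAMES[cls], "count": count,
                     "fraction": frac, "percent": int(round(100 * frac))})
    return pd.DataFrame(rows)


def distance_to_class(points: PointSet, riskmap: RiskMap,
                      target_class: int = HIGH) -> pd.DataFrame:
    """Euclidean distance (m) from each point to the nearest target-class
    cell center; points inside a target-class cell get 0."""
    target = (riskmap.classes == target_class) & riskmap.valid
    if not target.any():
        raise GridError("distance_to_class: no target-class cells")
    rows_t, cols_t = np.nonzero(target)
    cx, cy = riskmap.grid.cell_center(rows_t, cols_t)
    tree = cKDTree(np.column_stack([cx, cy]))
    xy = points.xy
    d, _ = tree.query(xy)
    r, c = riskmap.grid.point_to_cell(xy[:, 0], xy[:, 1])
    on = riskmap.grid.contains(xy[:, 0], xy[:, 1])
    inside = np.zeros(len(points), dtype=bool)
    inside[on] = target[r[on], c[on]]
    d = np.where(inside, 0.0, d)
    return pd.DataFrame({"id": points.df["id"], "distance_m": d})
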