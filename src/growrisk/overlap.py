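"""Overlap of moderate-high risk with habitat layers and home ranges.

Home ranges use the adaptive local convex hull (a-LoCoH) estimator: around
every location, a local hull is built from the nearest neighbors added in
distance order while their cumulative distance stays within the adaptive
parameter ``a`` (default: the maximum pairwise distance among the animal's
locations). Hulls are sorted by ascending area and unioned until the chosen
isopleth fraction of locations is covered; the 95% isopleth union is the
home range. Overlap statistics are computed on the rasterized range
(cell-center rule) so they are consistent with every other raster statistic
in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import MultiPoint

from .classify import MODERATE, RiskMap
from .io import GridError, PointSet, Raster

logger = logging.getLogger("growrisk")


@dataclass
class HomeRange:
    animal_id: str
    polygon: shapely.Geometry
    n_locations: int
    a_parameter: float
    isopleth: float
    coverage: float  # fraction of locations inside the returned polygon


@dataclass
class OverlapReport:
    per_unit: pd.DataFrame  # unit id, percent overlap
    mean: float
    sd: float
    minimum: float
    maximum: float
    n: int
    percent_with_overlap: float


def habitat_overlap(habitat: Raster, riskmap: RiskMap) -> float:
    """Percent of suitable habitat cells lying in moderate-to-high risk."""
    if habitat.grid != riskmap.grid:
        raise GridError("habitat and risk map must share the analysis grid")
    suitable = habitat.valid & (habitat.values != 0) & riskmap.valid
    n = int(suitable.sum())
    if n == 0:
        raise GridError("habitat_overlap: zero suitable cells")
    hit = int((riskmap.classes[suitable] >= MODERATE).sum())
    return 100.0 * hit / n


def alocoh_homerange(locations: PointSet, isopleth: float = 0.95,
                     a: float | None = None, min_locations: int = 26,
                     animal_id: str | None = None) -> HomeRange:
    """Adaptive LoCoH home range (isopleth of unioned local hulls).

    Duplicated coordinates collapse to one hull point but keep their
    multiplicity for isopleth coverage counting. Requires at least
    ``min_locations`` locations (the published rule: more than 25) and
    non-degenerate geometry.
    """
    n = len(locations)
    if n < min_locations:
        raise GridError(
            f"insufficient locations: {n} < {min_locations}")
    xy = locations.xy
    if np.ptp(xy[:, 0]) == 0 and np.ptp(xy[:, 1]) == 0:
        raise GridError("degenerate geometry: all locations identical")
    D = squareform(pdist(xy))
    if a is None:
        a = float(D.max())

    hulls = []
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        cum = np.cumsum(D[i][order[1:]])
        k = int(np.searchsorted(cum, a, side="right"))
        pts = xy[order[: k + 1]]
        hull = MultiPoint(pts).convex_hull
        hulls.append(hull)
    hulls.sort(key=lambda h: h.area)

    pts_geom = shapely.points(xy)
    covered = np.zeros(n, dtype=bool)
    union = None
    need = isopleth * n
    for h in hulls:
        union = h if union is None else union.union(h)
        covered = shapely.intersects(union, pts_geom)
        if covered.sum() >= need:
            break
    if union is None or union.area == 0:
        raise GridError("degenerate geometry: hulls have zero area")
    coverage = float(covered.sum() / n)
    return HomeRange(
        animal_id=animal_id or str(locations.df.get("group", pd.Series(["?"])).iloc[0]),
        polygon=union,
        n_locations=n,
        a_parameter=a,
        isopleth=isopleth,
        coverage=coverage,
    )


def _range_percent_overlap(polygon, riskmap: RiskMap) -> float | None:
    """Percent of a polygon's valid cells (cell-center rule) in mod-high."""
    X, Y = riskmap.grid.center_mesh()
    inside = shapely.intersects_xy(polygon, X, Y) & riskmap.valid
    n = int(inside.sum())
    if n == 0:
        return None
    return 100.0 * float((riskmap.classes[inside] >= MODERATE).mean())


def homerange_overlap(homeranges: list[HomeRange], riskmap: RiskMap) -> OverlapReport:
    """Per-home-range percent overlap with moderate-to-high risk, with mean,
    population SD, range, and the percent of ranges with any overlap.

    Ranges covering no valid grid cell are excluded with a warning.
    """
    if not homeranges:
        raise GridError("homerange_overlap: no home ranges supplied")
    rows = []
    for hr in homeranges:
        pct = _range_percent_overlap(hr.polygon, riskmap)
        if pct is None:
            logger.warning("home range %s has zero on-grid area; excluded", hr.animal_id)
            continue
        rows.append({"animal_id": hr.animal_id, "percent_overlap": pct,
                     "n_locations": hr.n_locations, "a_parameter": hr.a_parameter})
    if not rows:
        raise GridError("homerange_overlap: no home range overlaps the grid")
    df = pd.DataFrame(rows)
    pct = df["percent_overlap"].to_numpy()
    return OverlapReport(
        per_unit=df,
        mean=float(pct.mean()),
        sd=float(pct.std()),  # population SD
        minimum=float(pct.min()),
        maximum=float(pct.max()),
        n=len(pct),
        percent_with_overlap=100.0 * float((pct > 0).mean()),
    )
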