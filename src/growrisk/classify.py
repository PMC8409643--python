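"""Boyce-index analysis and low/moderate/high risk classification.

The continuous Boyce index compares, across sliding suitability windows, the
share of evaluation presences falling in the window (P, "predicted") to the
share of the landscape in it (E, "expected"). A suitability surface that
ranks presences correctly has a P/E curve increasing with suitability and a
Spearman correlation (the Boyce index) near 1.

Class thresholds sit where the P/E curve crosses meaningful levels:
presences occur at the expected rate at P/E = 1 (the low/moderate boundary)
and at twice it at P/E = 2 (moderate/high). The crossings use the *last*
upcrossing ("first reaches and stays at or above"), which guards against
noisy curves. Both thresholds can be overridden explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.stats import spearmanr

from .io import GridError, GridSpec, PointSet, Raster

logger = logging.getLogger("growrisk")

LOW, MODERATE, HIGH = 0, 1, 2
CLASS_NAMES = {LOW: "low", MODERATE: "moderate", HIGH: "high"}


@dataclass
class BoyceCurve:
    midpoints: np.ndarray
    pe_ratio: np.ndarray
    boyce_index: float


@dataclass
class ClassThresholds:
    t_low_mod: float
    t_mod_high: float

    def __post_init__(self):
        if not (0 < self.t_low_mod < self.t_mod_high):
            raise GridError(
                f"thresholds must satisfy 0 < t1 < t2, got "
                f"({self.t_low_mod}, {self.t_mod_high})"
            )


@dataclass
class RiskMap:
    """Per-cell class in {0: low, 1: moderate, 2: high} plus the thresholds
    and Boyce index used to derive it."""

    grid: "GridSpec"
    classes: np.ndarray
    nodata_mask: np.ndarray
    thresholds: ClassThresholds | None
    boyce_index: float | None = None
    source_model: str | None = None

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def class_raster(self) -> Raster:
        return Raster(self.grid, self.classes.astype(float), self.nodata_mask)


def boyce_curve(suitability: Raster, eval_presences: PointSet,
                window_width: float = 0.1, n_windows: int = 101) -> BoyceCurve:
    """Sliding-window P/E curve and its Spearman rank correlation with the
    window midpoint (the continuous Boyce index).

    Windows of ``window_width`` slide over [0, 1]; windows containing no
    landscape (E = 0) are dropped.
    """
    vals = suitability.values[suitability.valid]
    if vals.size == 0:
        raise GridError("boyce_curve: suitability has no valid cells")
    if np.ptp(vals) == 0:
        raise GridError("boyce_curve: constant suitability surface")
    pres = suitability.sample(eval_presences.xy[:, 0], eval_presences.xy[:, 1])
    pres = pres[np.isfinite(pres)]
    if pres.size < 10:
        raise GridError("boyce_curve needs at least 10 on-grid evaluation presences")

    starts = np.linspace(0.0, 1.0 - window_width, n_windows)
    mids, pe = [], []
    for s in starts:
        hi = s + window_width
        if hi >= 1.0 - 1e-12:
            in_win_cells = (vals >= s) & (vals <= hi)
            in_win_pres = (pres >= s) & (pres <= hi)
        else:
            in_win_cells = (vals >= s) & (vals < hi)
            in_win_pres = (pres >= s) & (pres < hi)
        E = in_win_cells.mean()
        if E == 0:
            continue
        P = in_win_pres.mean()
        mids.append(s + window_width / 2.0)
        pe.append(P / E)
    if not pe:
        raise GridError("boyce_curve: every window is empty")
    mids = np.array(mids)
    pe = np.array(pe)
    if np.ptp(pe) == 0:
        index = 0.0
    else:
        index = float(spearmanr(pe, mids).statistic)
    return BoyceCurve(midpoints=mids, pe_ratio=pe, boyce_index=index)


def _stays_above(curve: BoyceCurve, level: float) -> float | None:
    """Lowest midpoint from which the P/E curve stays >= level to the end
    (i.e. the last upcrossing).

    Trailing windows with zero presences are ignored: with a small
    evaluation sample the highest-suitability windows often hold a few
    cells but no presences at all, which says nothing against suitability
    yet would otherwise veto every threshold.
    """
    pe = curve.pe_ratio
    last = len(pe) - 1
    while last > 0 and pe[last] == 0:
        last -= 1
    above = pe[: last + 1] >= level
    if above.size == 0 or not above[-1]:
        return None
    i = above.size - 1
    while i > 0 and above[i - 1]:
        i -= 1
    return float(curve.midpoints[i])


def thresholds_from_curve(curve: BoyceCurve,
                          levels: tuple[float, float] = (1.0, 2.0)
                          ) -> tuple[float | None, float | None]:
    """Candidate thresholds at P/E = 1 (low/moderate) and P/E = 2
    (moderate/high); each is None where the curve never stays at the level."""
    return _stays_above(curve, levels[0]), _stays_above(curve, levels[1])


def classify_risk(suitability: Raster, curve: BoyceCurve | None = None,
                  overrides: ClassThresholds | None = None,
                  source_model: str | None = None) -> RiskMap:
    """Classify the logistic surface into low [0, t1), moderate [t1, t2),
    high [t2, 1] using Boyce-derived (or explicitly overridden) thresholds.

    If the P/E curve never reaches 1 there is no non-low class: a warning is
    logged and an all-low map returned. If the derived thresholds are not
    ordered, overrides are required.
    """
    if overrides is None and curve is None:
        raise GridError("classify_risk needs a Boyce curve or explicit thresholds")
    thresholds = overrides
    boyce = curve.boyce_index if curve is not None else None
    if thresholds is None:
        t1, t2 = thresholds_from_curve(curve)
        if t1 is None:
            logger.warning("classify_risk: P/E never reaches 1; all-low map")
            classes = np.zeros(suitability.grid.shape, dtype=np.uint8)
            return RiskMap(suitability.grid, classes, suitability.nodata_mask.copy(),
                           None, boyce, source_model)
        if t2 is None:
            # no high class: put the upper cut just beyond the surface range
            logger.warning("classify_risk: P/E never reaches 2; no high class")
            t2 = np.nextafter(1.0, 2.0)
        if t1 >= t2:
            raise GridError(
                f"derived thresholds not ordered (t1={t1}, t2={t2}); "
                "pass explicit overrides"
            )
        thresholds = ClassThresholds(t1, t2)

    v = suitability.values
    classes = np.zeros(suitability.grid.shape, dtype=np.uint8)
    classes[v >= thresholds.t_low_mod] = MODERATE
    classes[v >= thresholds.t_mod_high] = HIGH
    classes[suitability.nodata_mask] = 0
    return RiskMap(suitability.grid, classes, suitability.nodata_mask.copy(),
                   thresholds, boyce, source_model)


def class_areas(riskmap: RiskMap) -> pd.DataFrame:
    """Planar area (km^2) and percent of the non-nodata extent per class."""
    if not riskmap.valid.any():
        raise GridError("class_areas: empty risk map")
    cell_km2 = riskmap.grid.cell_area_km2()
    counts = np.array([
        int(((riskmap.classes == c) & riskmap.valid).sum()) for c in (LOW, MODERATE, HIGH)
    ])
    total = counts.sum()
    return pd.DataFrame({
        "class": [CLASS_NAMES[c] for c in (LOW, MODERATE, HIGH)],
        "n_cells": counts,
        "area_km2": counts * cell_km2,
        "percent": 100.0 * counts / total,
    })


def class_shares_from_areas(areas: dict[str, float] | pd.Series) -> pd.Series:
    """Percent of the extent per class from per-class areas (any area unit)."""
    s = pd.Series(areas, dtype=float)
    if (s < 0).any() or s.sum() <= 0:
        raise GridError("areas must be non-negative with a positive total")
    return 100.0 * s / s.sum()


def summarize_units(riskmap: RiskMap, units, unit_ids=None) -> pd.DataFrame:
    """Per summary-unit polygon, the proportion of its non-nodata cells in
    moderate-to-high risk. Units with zero overlapping cells are flagged with
    a NaN proportion."""
    if not isinstance(units, (list, tuple, np.ndarray)):
        units = [units]
    units = list(units)
    if unit_ids is None:
        unit_ids = [f"unit{i}" for i in range(len(units))]
    X, Y = riskmap.grid.center_mesh()
    rows = []
    for uid, geom in zip(unit_ids, units):
        inside = shapely.intersects_xy(geom, X, Y) & riskmap.valid
        n = int(inside.sum())
        if n == 0:
            logger.warning("summarize_units: unit %s overlaps no valid cells", uid)
            prop = np.nan
        else:
            prop = float((riskmap.classes[inside] >= MODERATE).mean())
        rows.append({"unit": uid, "n_cells": n, "prop_mod_high": prop})
    if not rows:
        raise GridError("summarize_units: no units supplied")
    return pd.DataFrame(rows)
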