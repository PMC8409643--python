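"""Data preparation: spatial thinning, background sampling, focal smoothing,
value extraction, and cross-validation folds.

Occurrences are thinned to a 2000 m minimum nearest-neighbor distance
(boundary inclusive) to reduce pseudo-replication from clustered enforcement
discoveries; background availability points are drawn uniformly over the
modeling extent and are deliberately *not* thinned. Predictors are averaged
over a 450 m radius moving window before extraction to match the positional
footprint of the locality data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .io import GridError, PointSet, PredictorStack, Raster

logger = logging.getLogger("growrisk")

# relative slack so that pairs at exactly the thinning distance are kept
_REL_TOL = 1e-9


@dataclass
class ThinResult:
    kept: PointSet
    removed: PointSet
    min_pairwise_distance: float


@dataclass
class SampleTable:
    """Extracted predictor values for presences and background.

    ``df`` has columns ``presence`` (1/0), ``id``, ``x``, ``y``, one column
    per predictor, and (for presences, once assigned) ``fold`` in 1..k.
    """

    df: pd.DataFrame
    variables: list[str]

    @property
    def presence_df(self) -> pd.DataFrame:
        return self.df[self.df["presence"] == 1]

    @property
    def background_df(self) -> pd.DataFrame:
        return self.df[self.df["presence"] == 0]

    def values(self, which: str = "all") -> np.ndarray:
        sub = {"all": self.df, "presence": self.presence_df,
               "background": self.background_df}[which]
        return sub[self.variables].to_numpy(dtype=float)


def thin_occurrences(points: PointSet, thin_distance: float = 2000.0,
                     seed=None) -> ThinResult:
    """Greedy most-crowded-first thinning with seeded tie-breaks.

    Repeatedly removes the point with the most neighbors closer than the
    thinning distance (strictly; pairs at exactly the distance are allowed),
    then re-adds any removed point that no longer conflicts, so the kept set
    is maximal: no removed point could be re-added without violating the
    constraint.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(points)
    if n == 0:
        raise GridError("cannot thin an empty point set")
    xy = points.xy
    limit = thin_distance * (1 - _REL_TOL)

    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=limit, output_type="ndarray")
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i, j in pairs:
        neighbors[i].add(j)
        neighbors[j].add(i)

    alive = np.ones(n, dtype=bool)
    counts = np.array([len(s) for s in neighbors])
    while counts[alive].max(initial=0) > 0:
        worst = counts[alive].max()
        tied = np.flatnonzero(alive & (counts == worst))
        drop = int(rng.choice(tied))
        alive[drop] = False
        counts[drop] = 0
        for j in neighbors[drop]:
            if alive[j]:
                counts[j] -= 1

    # maximality pass: re-add removed points that no longer conflict
    changed = True
    while changed:
        changed = False
        removed_idx = np.flatnonzero(~alive)
        rng.shuffle(removed_idx)
        for i in removed_idx:
            if not any(alive[j] for j in neighbors[i]):
                alive[i] = True
                changed = True

    kept_idx = np.flatnonzero(alive)
    removed_idx = np.flatnonzero(~alive)
    kept = points.subset(kept_idx)
    removed = points.subset(removed_idx) if removed_idx.size else points.subset([])
    if kept_idx.size > 1:
        kxy = xy[kept_idx]
        ktree = cKDTree(kxy)
        d, _ = ktree.query(kxy, k=2)
        min_d = float(d[:, 1].min())
    else:
        min_d = float("inf")
    logger.info("thin_occurrences: kept %d of %d (min pairwise %.1f m)",
                kept_idx.size, n, min_d)
    return ThinResult(kept, removed, min_d)


def sample_background(mask: Raster, n: int = 10000, seed=None) -> PointSet:
    """Uniform background points over eligible (nonzero, non-nodata) cells,
    with replacement across cells and uniform jitter within the cell."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid = mask.grid
    eligible = np.flatnonzero(mask.valid.ravel() & (mask.values.ravel() != 0))
    if eligible.size == 0:
        raise GridError("background mask has no eligible cells")
    chosen = rng.choice(eligible, size=n, replace=True)
    rows, cols = np.unravel_index(chosen, grid.shape)
    cx, cy = grid.cell_center(rows, cols)
    half = grid.cell_size / 2.0
    x = cx + rng.uniform(-half, half, size=n)
    y = cy + rng.uniform(-half, half, size=n)
    return PointSet.from_xy(x, y, ids=[f"bg{i}" for i in range(n)])


def _disk_footprint(radius: float, cell_size: float) -> np.ndarray:
    """Cells whose centers lie within ``radius`` of the focal cell center."""
    r_cells = int(np.floor(radius / cell_size))
    dr = np.arange(-r_cells, r_cells + 1)
    dd = np.add.outer(dr**2, dr**2) * cell_size**2
    return dd <= radius**2 + 1e-9


def focal_stat(raster: Raster, radius: float = 450.0, stat: str = "mean") -> Raster:
    """Moving-window mean or standard deviation over a circular window.

    The window holds every cell whose center lies within ``radius`` of the
    focal cell center; nodata cells are excluded and edge windows are
    truncated (no padding). Output is nodata only where the window is empty.
    """
    if stat not in ("mean", "std"):
        raise ValueError("stat must be 'mean' or 'std'")
    grid = raster.grid
    if radius < grid.cell_size / 2:
        raise GridError("focal radius must be at least half a cell")
    if not raster.valid.any():
        raise GridError("focal_stat: all-nodata input")
    fp = _disk_footprint(radius, grid.cell_size).astype(float)
    valid = raster.valid.astype(float)
    vals = np.where(raster.valid, raster.values, 0.0)
    kw = dict(mode="constant", cval=0.0)
    count = ndi.correlate(valid, fp, **kw)
    total = ndi.correlate(vals, fp, **kw)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / count
    empty = count < 0.5
    if stat == "mean":
        out = mean
    else:
        total2 = ndi.correlate(vals**2, fp, **kw)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = total2 / count - mean**2
        out = np.sqrt(np.maximum(var, 0.0))
    out = out.copy()
    out[empty] = np.nan
    return Raster(grid, out, empty)


def smooth_stack(stack: PredictorStack, radius: float = 450.0) -> PredictorStack:
    """Focal-mean every layer of the stack (the published 450 m averaging)."""
    out = PredictorStack(stack.grid)
    for name, layer in stack.layers.items():
        out.add(name, focal_stat(layer, radius=radius, stat="mean"))
    return out


def extract_values(stack: PredictorStack, points: PointSet) -> pd.DataFrame:
    """One row of predictor values per point (containing-cell rule); rows
    hitting nodata in any layer are dropped with a logged count."""
    xy = points.xy
    data = {"id": points.df["id"].to_numpy(), "x": xy[:, 0], "y": xy[:, 1]}
    for name, layer in stack.layers.items():
        data[name] = layer.sample(xy[:, 0], xy[:, 1])
    df = pd.DataFrame(data)
    var_cols = stack.names
    good = df[var_cols].notna().all(axis=1)
    n_drop = int((~good).sum())
    if n_drop:
        logger.info("extract_values: dropped %d row(s) hitting nodata", n_drop)
    df = df[good].reset_index(drop=True)
    if len(df) == 0:
        raise GridError("extract_values: no rows survive nodata filtering")
    return df


def build_sample_table(stack: PredictorStack, presences: PointSet,
                       background: PointSet) -> SampleTable:
    """Extract presence and background rows into one modeling table."""
    p = extract_values(stack, presences)
    b = extract_values(stack, background)
    p.insert(0, "presence", 1)
    b.insert(0, "presence", 0)
    b["id"] = ["bg_" + str(i) for i in b["id"]]
    df = pd.concat([p, b], ignore_index=True)
    return SampleTable(df, stack.names)


def make_cv_folds(n_presences: int, k: int = 10, seed=None) -> np.ndarray:
    """Random partition of presences into k folds with sizes differing by at
    most one; labels are 1..k."""
    if n_presences < k:
        raise GridError(f"need at least {k} presences for {k}-fold CV, got {n_presences}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = np.tile(np.arange(1, k + 1), n_presences // k + 1)[:n_presences]
    rng.shuffle(labels)
    return labels


def assign_folds(table: SampleTable, k: int = 10, seed=None) -> SampleTable:
    """Attach fold labels to the presence rows of a sample table."""
    df = table.df.copy()
    pres = df["presence"] == 1
    labels = make_cv_folds(int(pres.sum()), k=k, seed=seed)
    df["fold"] = np.nan
    df.loc[pres, "fold"] = labels
    return SampleTable(df, table.variables)
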