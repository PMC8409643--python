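"""Grid model and geospatial I/O.

All analysis happens on a single projected grid (units = meters). Rasters are
stored as ESRI ASCII grids (plain text, ``.asc``) with a small JSON sidecar
carrying the CRS identifier; vectors are GeoJSON; point localities are CSV.

Coordinate conventions
----------------------
Cells are addressed by (row, col) with row 0 at the *top* of the grid.
Values live at cell centers. A point is assigned to the cell whose half-open
interval ``[x0, x0 + cell)`` x ``(y0 - cell, y0]`` contains it, so every
in-bounds point belongs to exactly one cell. Areas are planar:
``n_cells * cell_size**2``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage as ndi
from shapely.geometry import shape as geojson_shape

logger = logging.getLogger("growrisk")

NODATA = -9999.0


class GridError(ValueError):
    """Raised for grid/CRS mismatches, empty layers, and unreadable inputs."""


# ---------------------------------------------------------------------------
# Grid specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A projected analysis grid.

    Parameters
    ----------
    crs_id : projected CRS identifier (e.g. ``"EPSG:3310"``, California
        Albers); units must be meters. Geographic CRS are not supported.
    origin_x, origin_y : coordinates of the *top-left corner* of the grid, m.
    cell_size : cell edge length in meters (default 90).
    n_rows, n_cols : grid dimensions.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 90.0
    origin_x: float = 0.0
    origin_y: float | None = None
    crs_id: str = "EPSG:3310"

    def __post_init__(self):
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and one column")
        if self.origin_y is None:
            # default: bottom edge at y = 0
            object.__setattr__(self, "origin_y", self.n_rows * self.cell_size)

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (n_rows, n_cols) with cell-center coords."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def point_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Containing cell of each point (may be out of range; see contains)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.point_to_cell(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6


# ---------------------------------------------------------------------------
# Raster and stacks
# ---------------------------------------------------------------------------

@dataclass
class Raster:
    """A single-band raster on a :class:`GridSpec`.

    ``nodata_mask`` is True where the cell has no data; such cells are
    excluded from every statistic in the package.
    """

    grid: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.grid.shape:
                raise GridError("nodata_mask shape != grid shape")

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    @classmethod
    def full(cls, grid: GridSpec, value: float = 0.0) -> "Raster":
        return cls(grid, np.full(grid.shape, value, dtype=float))

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.nodata_mask.copy())

    def masked(self) -> np.ndarray:
        """Values with nodata as NaN."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out

    def sample(self, x, y) -> np.ndarray:
        """Value of the containing cell; NaN for off-grid or nodata points."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.grid.point_to_cell(x, y)
        ok = self.grid.contains(x, y)
        out = np.full(x.shape, np.nan)
        r, c = row[ok], col[ok]
        vals = self.values[r, c].astype(float)
        vals[self.nodata_mask[r, c]] = np.nan
        out[ok] = vals
        return out


@dataclass
class PredictorStack:
    """Named, grid-aligned environmental rasters."""

    grid: GridSpec
    layers: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self):
        for name, r in self.layers.items():
            if r.grid != self.grid:
                raise GridError(f"layer {name!r} is not on the stack grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def add(self, name: str, raster: Raster) -> None:
        if raster.grid != self.grid:
            raise GridError(f"layer {name!r} is not on the stack grid")
        if name in self.layers:
            raise GridError(f"duplicate layer name {name!r}")
        self.layers[name] = raster

    def subset(self, names: Sequence[str]) -> "PredictorStack":
        return PredictorStack(self.grid, {n: self.layers[n] for n in names})

    def combined_valid(self) -> np.ndarray:
        """Cells valid in every layer."""
        ok = np.ones(self.grid.shape, dtype=bool)
        for r in self.layers.values():
            ok &= r.valid
        return ok


# ---------------------------------------------------------------------------
# Point sets
# ---------------------------------------------------------------------------

@dataclass
class PointSet:
    """Projected point localities with ids and optional year/group labels."""

    df: pd.DataFrame  # columns: id, x, y [, year, group]

    def __post_init__(self):
        for col in ("id", "x", "y"):
            if col not in self.df.columns:
                raise GridError(f"PointSet requires column {col!r}")
        xy = self.df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise GridError("PointSet coordinates must be finite")
        if self.df["id"].duplicated().any():
            raise GridError("PointSet ids must be unique")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_xy(cls, x, y, ids=None, **extra) -> "PointSet":
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if ids is None:
            ids = [f"p{i}" for i in range(len(x))]
        data = {"id": list(ids), "x": x, "y": y}
        for k, v in extra.items():
            data[k] = v
        return cls(pd.DataFrame(data))

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, index) -> "PointSet":
        return PointSet(self.df.iloc[np.asarray(index)].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stream networks
# ---------------------------------------------------------------------------

@dataclass
class StreamNetwork:
    """Named stream reaches with summary-unit labels.

    ``table`` has columns ``reach_id``, ``name`` (stream name, shared by the
    reaches of one stream), ``unit`` (sub-watershed label) and ``length_km``;
    ``geometries`` holds the matching shapely LineStrings.
    """

    table: pd.DataFrame
    geometries: list

    def __post_init__(self):
        need = {"reach_id", "name", "unit"}
        if not need.issubset(self.table.columns):
            raise GridError(f"StreamNetwork table requires columns {sorted(need)}")
        if len(self.table) != len(self.geometries):
            raise GridError("StreamNetwork table and geometries differ in length")
        if "length_km" not in self.table.columns:
            self.table = self.table.copy()
            self.table["length_km"] = [g.length / 1000.0 for g in self.geometries]

    def __len__(self) -> int:
        return len(self.table)

    @property
    def total_km(self) -> float:
        return float(self.table["length_km"].sum())

    def to_geojson(self, path) -> None:
        write_geojson(self.geometries, path, self.table.to_dict("records"))

    @classmethod
    def from_geojson(cls, path) -> "StreamNetwork":
        geoms, props = read_geojson(path)
        return cls(pd.DataFrame(props), geoms)


# ---------------------------------------------------------------------------
# Raster file I/O (ESRI ASCII grid + CRS sidecar)
# ---------------------------------------------------------------------------

def write_raster(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (.asc) plus a ``.aux.json`` CRS sidecar.

    Values are written with 17 significant digits so a write/read round trip
    reproduces float64 values bit-exactly.
    """
    path = Path(path)
    g = raster.grid
    vals = raster.values.copy()
    vals[raster.nodata_mask] = NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin_x!r}\n")
        fh.write(f"yllcorner {g.origin_y - g.n_rows * g.cell_size!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA:g}\n")
        np.savetxt(fh, vals, fmt="%.17g")
    with open(path.with_suffix(path.suffix + ".aux.json"), "w") as fh:
        json.dump({"crs_id": g.crs_id}, fh)


def read_raster(path, crs_id: str | None = None) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_raster` (or any tool)."""
    path = Path(path)
    if not path.exists():
        raise GridError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        vals = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridError(f"missing header field {key!r} in {path}")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    if vals.shape != (n_rows, n_cols):
        raise GridError(f"data shape {vals.shape} does not match header in {path}")
    if crs_id is None:
        aux = path.with_suffix(path.suffix + ".aux.json")
        if aux.exists():
            crs_id = json.loads(aux.read_text()).get("crs_id")
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        crs_id=crs_id or "EPSG:3310",
    )
    nodata = header.get("nodata_value", NODATA)
    mask = vals == nodata
    vals = vals.copy()
    vals[mask] = np.nan
    return Raster(grid, vals, mask)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Alignment / stack loading
# ---------------------------------------------------------------------------

def align_to_grid(raster: Raster, grid: GridSpec) -> Raster:
    """Resample a raster onto ``grid`` (bilinear, for continuous values).

    A raster already on the target grid is returned as an identical copy, so
    alignment is idempotent. The source must share the target CRS (on-the-fly
    reprojection is out of scope) and overlap the target extent.
    """
    src = raster.grid
    if src.crs_id != grid.crs_id:
        raise GridError(f"CRS mismatch: {src.crs_id} vs {grid.crs_id}")
    if src == grid:
        return raster.copy()

    X, Y = grid.center_mesh()
    # fractional source array indices of target cell centers
    ci = (X - src.origin_x) / src.cell_size - 0.5
    ri = (src.origin_y - Y) / src.cell_size - 0.5
    inside = (
        (ci > -0.5) & (ci < src.n_cols - 0.5) & (ri > -0.5) & (ri < src.n_rows - 0.5)
    )
    if not inside.any():
        raise GridError("source raster does not overlap the target grid")

    valid = raster.valid.astype(float)
    filled = np.where(raster.valid, raster.values, 0.0)
    coords = np.vstack([ri.ravel(), ci.ravel()])
    num = ndi.map_coordinates(filled, coords, order=1, mode="nearest").reshape(grid.shape)
    den = ndi.map_coordinates(valid, coords, order=1, mode="nearest").reshape(grid.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    mask = (~inside) | (den < 0.5)
    out[mask] = np.nan
    return Raster(grid, out, mask)


def load_stack(paths, grid: GridSpec, names: Sequence[str] | None = None) -> PredictorStack:
    """Load raster files and align every layer to the analysis grid.

    ``paths`` is a list of file paths or a mapping name -> path; names default
    to file stems.
    """
    if isinstance(paths, Mapping):
        items = list(paths.items())
    else:
        items = [(Path(p).stem, p) for p in paths]
        if names is not None:
            items = list(zip(names, [p for _, p in items]))
    stack = PredictorStack(grid)
    for name, p in items:
        stack.add(name, align_to_grid(read_raster(p), grid))
    return stack


# ---------------------------------------------------------------------------
# Points loading
# ---------------------------------------------------------------------------

def load_points(path, grid: GridSpec) -> PointSet:
    """Read point localities from CSV (x,y[,id,year]) or GeoJSON points.

    Points outside the grid bounding box are excluded with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise GridError(f"points file not found: {path}")
    if path.suffix.lower() in {".json", ".geojson"}:
        df = _points_from_geojson(path)
    else:
        df = pd.read_csv(path)
        df.columns = [c.lower() for c in df.columns]
    if "x" not in df.columns or "y" not in df.columns or len(df) == 0:
        raise GridError(f"no parseable coordinates in {path}")
    if "id" not in df.columns:
        df["id"] = [f"p{i}" for i in range(len(df))]
    inb = grid.contains(df["x"].to_numpy(float), df["y"].to_numpy(float))
    n_out = int((~inb).sum())
    if n_out:
        logger.info("load_points: excluded %d point(s) outside the grid", n_out)
    df = df[inb].reset_index(drop=True)
    if len(df) == 0:
        raise GridError(f"no points from {path} fall inside the grid")
    return PointSet(df)


def _points_from_geojson(path: Path) -> pd.DataFrame:
    gj = json.loads(Path(path).read_text())
    feats = gj.get("features", [])
    rows = []
    for f in feats:
        geom = f.get("geometry") or {}
        if geom.get("type") != "Point":
            continue
        x, y = geom["coordinates"][:2]
        row = {"x": float(x), "y": float(y)}
        row.update(f.get("properties") or {})
        rows.append(row)
    if not rows:
        raise GridError(f"no point features in {path}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Vector I/O helpers (GeoJSON)
# ---------------------------------------------------------------------------

def write_geojson(geometries: Iterable, path, properties: Sequence[dict] | None = None) -> None:
    geometries = list(geometries)
    if properties is None:
        properties = [{} for _ in geometries]
    feats = [
        {"type": "Feature", "geometry": shapely.geometry.mapping(g), "properties": p}
        for g, p in zip(geometries, properties)
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_geojson(path) -> tuple[list, list[dict]]:
    gj = json.loads(Path(path).read_text())
    geoms, props = [], []
    for f in gj.get("features", []):
        if f.get("geometry") is None:
            continue
        geoms.append(geojson_shape(f["geometry"]))
        props.append(f.get("properties") or {})
    return geoms, props


# ---------------------------------------------------------------------------
# Rasterization and distance transforms
# ---------------------------------------------------------------------------

def rasterize(geometries, grid: GridSpec) -> Raster:
    """Burn vector geometries onto the grid.

    A cell is foreground iff its center is covered by a polygon, or lies
    within ``cell_size / 2`` of a line. Point geometries mark their containing
    cell.
    """
    if not isinstance(geometries, (list, tuple, np.ndarray)):
        geometries = [geometries]
    geometries = [g for g in geometries if g is not None and not g.is_empty]
    if not geometries:
        raise GridError("cannot rasterize an empty vector layer")
    for g in geometries:
        if not shapely.is_valid(g):
            raise GridError("invalid geometry in vector layer")

    fg = np.zeros(grid.shape, dtype=bool)
    X, Y = grid.center_mesh()
    polys = [g for g in geometries if g.geom_type in ("Polygon", "MultiPolygon")]
    lines = [g for g in geometries if g.geom_type in ("LineString", "MultiLineString")]
    points = [g for g in geometries if g.geom_type in ("Point", "MultiPoint")]
    if polys:
        union = shapely.union_all(polys)
        fg |= shapely.intersects_xy(union, X, Y)
    if lines:
        union = shapely.union_all(lines)
        centers = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
        d = shapely.distance(union, centers).reshape(grid.shape)
        fg |= d <= grid.cell_size / 2
    for g in points:
        coords = shapely.get_coordinates(g)
        r, c = grid.point_to_cell(coords[:, 0], coords[:, 1])
        ok = (r >= 0) & (r < grid.n_rows) & (c >= 0) & (c < grid.n_cols)
        fg[r[ok], c[ok]] = True
    return Raster(grid, fg.astype(float))


def distance_transform(source, grid: GridSpec | None = None) -> Raster:
    """Euclidean distance (m) from every cell center to the nearest
    foreground cell center; foreground cells get 0.

    ``source`` is a binary Raster (foreground = nonzero valid cells) or
    vector geometries, which are rasterized first.
    """
    if isinstance(source, Raster):
        raster = source
    else:
        if grid is None:
            raise GridError("grid is required when source is a vector layer")
        raster = rasterize(source, grid)
    fg = raster.valid & (raster.values != 0)
    if not fg.any():
        raise GridError("distance_transform: empty foreground")
    dist = ndi.distance_transform_edt(~fg, sampling=raster.grid.cell_size)
    return Raster(raster.grid, dist)
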