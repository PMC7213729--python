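"""Depth-stratified survey frame (grid) construction and I/O.

A survey grid is a regular raster of square cells, each carrying a depth, a
cell id, a management division and a survey stratum.  Generated grids vary
depth along the x-axis only: a monotone ramp from d_min to d_max with a flat
shelf of width ``shelf_width`` at ``shelf_depth`` (linear when shelf_width is
zero).  Divisions partition the y-axis into equal bands; strata are depth
classes (between successive ``strat_breaks``), each optionally split into
equal y-bands within a division.

Real-world frames can be supplied instead: ``load_grid`` accepts a CSV cell
table or a NetCDF raster with layers depth/cell/division/strat on projected
(equal-area, km) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GridParams", "SurveyGrid", "make_grid", "load_grid", "save_grid",
           "strat_areas", "depth_profile"]

_LAYERS = ("x", "y", "depth", "cell", "division", "strat")


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class GridParams:
    """Survey-frame geometry; distances in km, depths in m."""

    x_range: tuple = (-140.0, 140.0)
    y_range: tuple = (-140.0, 140.0)
    res: tuple = (3.5, 3.5)
    shelf_depth: float = 200.0
    shelf_width: float = 100.0
    depth_range: tuple = (0.0, 1000.0)
    n_div: int = 1
    strat_splits: int = 2
    strat_breaks: tuple = tuple(float(b) for b in range(0, 1001, 40))

    def __post_init__(self):
        for rng, res in ((self.x_range, self.res[0]), (self.y_range, self.res[1])):
            extent = rng[1] - rng[0]
            if extent <= 0 or res <= 0:
                raise GridError("ranges must be increasing and res positive")
            if abs(extent / res - round(extent / res)) > 1e-9:
                raise GridError(f"extent {extent} not divisible by resolution {res}")
        d_min, d_max = self.depth_range
        if not d_min < d_max:
            raise GridError("depth_range must satisfy d_min < d_max")
        breaks = np.asarray(self.strat_breaks, dtype=float)
        if breaks.size < 2 or np.any(np.diff(breaks) <= 0):
            raise GridError("strat_breaks must be strictly increasing with >= 2 entries")
        if breaks[0] > d_min or breaks[-1] < d_max:
            raise GridError("strat_breaks must span depth_range")
        if self.n_div < 1:
            raise GridError("n_div must be >= 1")
        if self.strat_splits < 0:
            raise GridError("strat_splits must be >= 0")
        if self.shelf_width < 0:
            raise GridError("shelf_width must be >= 0")


def depth_profile(x, params: GridParams) -> np.ndarray:
    """Monotone depth-vs-x profile.

    Linear ramp from d_min to d_max when shelf_width == 0; otherwise a flat
    shelf of the given width at shelf_depth, centred where the linear ramp
    crosses shelf_depth, with linear limbs to d_min and d_max on either side.
    """
    x = np.asarray(x, dtype=float)
    x0, x1 = params.x_range
    d_min, d_max = params.depth_range
    lin = d_min + (d_max - d_min) * (x - x0) / (x1 - x0)
    w = params.shelf_width
    if w == 0:
        return lin
    d_sh = params.shelf_depth
    xc = x0 + (x1 - x0) * (d_sh - d_min) / (d_max - d_min)
    xl = max(x0, xc - w / 2.0)
    xr = min(x1, xc + w / 2.0)
    d = np.full_like(x, d_sh)
    left = x < xl
    right = x > xr
    if xl > x0:
        d[left] = d_min + (d_sh - d_min) * (x[left] - x0) / (xl - x0)
    else:
        d[left] = d_min
    if xr < x1:
        d[right] = d_sh + (d_max - d_sh) * (x[right] - xr) / (x1 - xr)
    else:
        d[right] = d_max
    return d


@dataclass(frozen=True)
class SurveyGrid:
    """Cell table (x, y, depth, cell, division, strat) plus the cell area (km^2)."""

    cells: pd.DataFrame = field(repr=False)
    cell_area: float

    def __post_init__(self):
        c = self.cells
        missing = [k for k in _LAYERS if k not in c.columns]
        if missing:
            raise GridError(f"grid is missing layer(s): {', '.join(missing)}")
        if c["cell"].duplicated().any():
            raise GridError("cell ids must be unique")
        per_cell = c.groupby("cell")[["division", "strat"]].nunique()
        if (per_cell > 1).any().any():
            raise GridError("each cell must have exactly one division and one stratum")
        strat_div = c.groupby("strat")["division"].nunique()
        if (strat_div > 1).any():
            raise GridError("each stratum must lie in a single division")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_area(self) -> float:
        return self.n_cells * self.cell_area

    def strat_areas(self) -> pd.DataFrame:
        return strat_areas(self)


def strat_areas(grid: SurveyGrid) -> pd.DataFrame:
    """Area of each stratum: member-cell count times the cell area."""
    tab = (grid.cells.groupby(["division", "strat"], sort=True)
           .size().rename("n_cells").reset_index())
    tab["area"] = tab["n_cells"] * grid.cell_area
    return tab


def make_grid(params: GridParams | None = None) -> SurveyGrid:
    """Construct a regular depth-stratified grid from its geometry parameters."""
    p = params if params is not None else GridParams()
    rx, ry = p.res
    nx = int(round((p.x_range[1] - p.x_range[0]) / rx))
    ny = int(round((p.y_range[1] - p.y_range[0]) / ry))
    xs = p.x_range[0] + rx * (0.5 + np.arange(nx))
    ys = p.y_range[0] + ry * (0.5 + np.arange(ny))
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    x = X.ravel()
    y = Y.ravel()
    depth = depth_profile(x, p)

    # divisions: equal y-bands, numbered 1..n_div from the bottom
    y_extent = p.y_range[1] - p.y_range[0]
    division = 1 + np.minimum(
        ((y - p.y_range[0]) / (y_extent / p.n_div)).astype(int), p.n_div - 1)

    # depth classes: left-open/right-closed intervals of strat_breaks,
    # the lowest break closed so the shallow boundary is included
    breaks = np.asarray(p.strat_breaks, dtype=float)
    klass = np.searchsorted(breaks, depth, side="left") - 1
    klass[depth == breaks[0]] = 0
    orphan = (klass < 0) | (klass >= breaks.size - 1)
    if orphan.any():
        ids = np.flatnonzero(orphan)[:10]
        raise GridError(
            f"strat_breaks do not cover observed depths; e.g. cells {ids.tolist()} "
            f"with depths {np.round(depth[orphan][:10], 2).tolist()}")

    # splits: each (division, depth class) split into equal y-bands
    n_split = max(1, p.strat_splits)
    div_y0 = p.y_range[0] + (division - 1) * (y_extent / p.n_div)
    piece = np.minimum(((y - div_y0) / (y_extent / p.n_div / n_split)).astype(int),
                       n_split - 1)

    # stable stratum coding: sort by (division, depth class, split piece)
    combo = pd.DataFrame({"division": division, "klass": klass, "piece": piece})
    keys = combo.drop_duplicates().sort_values(["division", "klass", "piece"])
    keys = keys.reset_index(drop=True)
    keys["strat"] = np.arange(1, len(keys) + 1)
    combo = combo.merge(keys, on=["division", "klass", "piece"], how="left")

    cells = pd.DataFrame({
        "x": x, "y": y, "depth": depth,
        "cell": np.arange(1, x.size + 1),
        "division": division,
        "strat": combo["strat"].to_numpy(),
    })
    return SurveyGrid(cells=cells, cell_area=rx * ry)


def _infer_res(vals: np.ndarray) -> float:
    u = np.unique(vals)
    if u.size < 2:
        raise GridError("cannot infer cell size from a single coordinate")
    d = np.diff(u)
    if not np.allclose(d, d[0], rtol=1e-6):
        raise GridError("grid coordinates are not regularly spaced")
    return float(d[0])


def _check_projected(x: np.ndarray, y: np.ndarray, attrs: dict) -> None:
    units = str(attrs.get("units", "")).lower()
    crs = str(attrs.get("crs", "")).lower()
    if "degree" in units or "4326" in crs or "longlat" in crs:
        raise GridError("grid coordinates are geographic (degrees); an equal-area "
                        "projection in km is required")


def save_grid(grid: SurveyGrid, path) -> None:
    """Write a grid as a CSV cell table or a NetCDF raster (by extension)."""
    path = Path(path)
    if path.suffix == ".csv":
        grid.cells.to_csv(path, index=False)
    elif path.suffix == ".nc":
        import xarray as xr
        c = grid.cells.set_index(["y", "x"]).sort_index()
        ds = xr.Dataset({k: c[k].to_xarray() for k in ("depth", "cell", "division", "strat")})
        ds.attrs["cell_area"] = grid.cell_area
        ds.to_netcdf(path, engine="scipy")
    else:
        raise GridError(f"unsupported grid format: {path.suffix} (use .csv or .nc)")


def load_grid(path) -> SurveyGrid:
    """Read and validate a survey grid from CSV or NetCDF; cell area is inferred
    from the coordinate spacing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".csv":
        cells = pd.read_csv(path)
        missing = [k for k in _LAYERS if k not in cells.columns]
        if missing:
            raise GridError(f"grid file missing layer(s): {', '.join(missing)}")
        _check_projected(cells["x"].to_numpy(), cells["y"].to_numpy(), {})
        area = _infer_res(cells["x"].to_numpy()) * _infer_res(cells["y"].to_numpy())
        for col in ("cell", "division", "strat"):
            cells[col] = cells[col].astype(int)
        return SurveyGrid(cells=cells.reset_index(drop=True), cell_area=area)
    if path.suffix == ".nc":
        import xarray as xr
        ds = xr.open_dataset(path, engine="scipy")
        missing = [k for k in ("depth", "cell", "division", "strat") if k not in ds]
        if missing:
            raise GridError(f"grid file missing layer(s): {', '.join(missing)}")
        attrs = dict(ds.attrs)
        for coord in ("x", "y"):
            if coord in ds.coords:
                attrs.update(ds[coord].attrs)
        df = ds.to_dataframe().reset_index()
        ds.close()
        df = df.dropna(subset=["cell"])
        _check_projected(df["x"].to_numpy(), df["y"].to_numpy(), attrs)
        area = _infer_res(df["x"].to_numpy()) * _infer_res(df["y"].to_numpy())
        for col in ("cell", "division", "strat"):
            df[col] = df[col].astype(int)
        cols = ["x", "y", "depth", "cell", "division", "strat"]
        return SurveyGrid(cells=df[cols].reset_index(drop=True), cell_area=area)
    raise GridError(f"unsupported grid format: {path.suffix} (use .csv or .nc)")
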