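"""Synthetic estuary scenes with known structure.

The scene is schematic: a rectangular estuary open to the sea on its
southern edge, fed by three rivers (A, B, C) entering from the north,
mirroring a Caloosahatchee / Myakka / Peace configuration.  Only the
covariate structure matters for the statistics, not cartography: depth
shoals toward shore, mangroves concentrate along shorelines and around
river mouths, one river carries a developed (hardened) shoreline
stretch, and every 200-m "microgrid" cell knows its river, its signed
along-channel distance to the river mouth (negative seaward), and its
habitat covariates computed through the raster toolchain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from . import rasters as rmod
from .tweedie import rng_from_seed

RIVER_NAMES = ("A", "B", "C")


@dataclass
class EstuaryConfig:
    """Geometry and habitat parameters of the synthetic estuary.

    The lattice is ``nx`` x ``ny`` square cells of ``cell_m`` metres
    (default 200 m, the microgrid size).  Rivers are vertical channels
    entering from the north; ``mouth_row`` is the first open-estuary row.
    """

    nx: int = 36
    ny: int = 30
    cell_m: float = 200.0
    mouth_row: int = 12  # rows 0..mouth_row-1 are riverine
    river_cols: dict = field(default_factory=lambda: {"A": 5, "B": 17, "C": 29})
    river_halfwidth: dict = field(default_factory=lambda: {"A": 2, "B": 1, "C": 2})
    developed_river: str = "A"
    developed_rows: tuple = (4, 9)  # mid-river stretch with hardened shoreline
    max_depth_m: float = 6.0
    mangrove_fraction: float = 0.35  # shoreline-zone mangrove cover
    sub_factor: int = 8  # mangrove raster pixels per cell side
    shore_buffer_m: float | None = None  # distance-to-shore buffer; default 3 pixels

    def __post_init__(self):
        if self.cell_m <= 0:
            raise ValueError("cell size must be positive")
        if self.nx < 4 or self.ny < 4:
            raise ValueError("grid must be at least 4 x 4")
        if not self.river_cols:
            raise ValueError("at least one river required")

    @property
    def pixel_m(self) -> float:
        return self.cell_m / self.sub_factor


@dataclass
class EstuaryScene:
    """Generated estuary: cell table, rasters, geometry, ground truth."""

    config: EstuaryConfig
    cells: pd.DataFrame  # one row per water cell
    depth: rmod.Raster  # cell-resolution bathymetry
    mangrove: rmod.Raster  # sub-cell binary mangrove raster
    mangrove_distance: rmod.Raster
    mangrove_focal: rmod.Raster
    shoreline: shapely.Geometry
    water_polygon: shapely.Geometry
    microgrids: list  # shapely boxes, indexed by microgrid_id

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_xy(self) -> np.ndarray:
        return self.cells[["x", "y"]].to_numpy()


def _water_mask(cfg: EstuaryConfig) -> np.ndarray:
    """Boolean (ny, nx) water mask: open estuary south, river strips north."""
    water = np.zeros((cfg.ny, cfg.nx), dtype=bool)
    water[cfg.mouth_row:, :] = True
    for name, c in cfg.river_cols.items():
        hw = cfg.river_halfwidth.get(name, 1)
        water[: cfg.mouth_row, max(c - hw, 0): c + hw + 1] = True
    return water


def generate_scene(config: EstuaryConfig | None = None, seed: int = 0) -> EstuaryScene:
    """Build a deterministic synthetic estuary for the given seed."""
    cfg = config or EstuaryConfig()
    rng = rng_from_seed([int(seed), 11])
    ny, nx, cell = cfg.ny, cfg.nx, cfg.cell_m
    water = _water_mask(cfg)

    # --- geometry: water polygon and shoreline -------------------------
    cell_boxes = {}
    squares = []
    for r, c in zip(*np.nonzero(water)):
        x0, y1 = c * cell, (ny - r) * cell  # origin upper-left, y down
        b = box(x0, y1 - cell, x0 + cell, y1)
        squares.append(b)
        cell_boxes[(r, c)] = b
    water_poly = unary_union(squares)
    # the southern edge is the open sea mouth, not a shore
    boundary = water_poly.boundary
    sea_edge = shapely.LineString([(0, 0), (nx * cell, 0)])
    shoreline = shapely.difference(boundary, sea_edge.buffer(1e-6))

    # --- river assignment and signed distance to river mouth -----------
    rows, cols = np.nonzero(water)
    xs = (cols + 0.5) * cell
    ys = (ny - rows - 0.5) * cell
    mouth_y = (ny - cfg.mouth_row) * cell
    river_x = {n: (c + 0.5) * cell for n, c in cfg.river_cols.items()}
    in_river = rows < cfg.mouth_row
    river_id = np.empty(len(rows), dtype=object)
    dist_rm = np.empty(len(rows))
    for i, (r, c, x, y) in enumerate(zip(rows, cols, xs, ys)):
        if in_river[i]:
            name = min(river_x, key=lambda n: abs(river_x[n] - x))
            river_id[i] = name
            dist_rm[i] = y - mouth_y  # along-channel, positive upriver
        else:
            name = min(river_x, key=lambda n: np.hypot(river_x[n] - x, mouth_y - y))
            river_id[i] = name
            dist_rm[i] = -float(np.hypot(river_x[name] - x, mouth_y - y))

    # --- bathymetry: shoals toward shore -------------------------------
    depth_grid = np.full((ny, nx), np.nan)
    pts = shapely.points(xs, ys)
    d_shore = shapely.distance(pts, shoreline)
    scale = 5.0 * cell
    base = cfg.max_depth_m * np.tanh(d_shore / scale)
    base = base + rng.normal(0, 0.15, size=base.shape)
    base = np.clip(base, 0.2, cfg.max_depth_m)
    depth_grid[rows, cols] = base
    depth = rmod.Raster(depth_grid, x0=0.0, y0=ny * cell, cell=cell)

    # --- developed shoreline flag --------------------------------------
    dev = np.zeros(len(rows), dtype=bool)
    r0, r1 = cfg.developed_rows
    dev_river = cfg.developed_river
    dev |= (river_id == dev_river) & in_river & (rows >= r0) & (rows <= r1)

    # --- mangrove raster (sub-cell) ------------------------------------
    sub = cfg.sub_factor
    px = cfg.pixel_m
    H, W = ny * sub, nx * sub
    water_px = np.kron(water, np.ones((sub, sub), dtype=bool))
    pxs = (np.arange(W) + 0.5) * px
    pys = (ny * cell) - (np.arange(H) + 0.5) * px
    PX, PY = np.meshgrid(pxs, pys)
    # mangroves hug the shoreline: distance of each water pixel to shore
    wrow, wcol = np.nonzero(water_px)
    ppts = shapely.points(PX[wrow, wcol], PY[wrow, wcol])
    pd_shore = shapely.distance(ppts, shoreline)
    # and concentrate around river mouths
    mouth_pts = shapely.points(
        [river_x[n] for n in cfg.river_cols], [mouth_y] * len(cfg.river_cols)
    )
    d_mouth = np.min(
        [shapely.distance(ppts, mp) for mp in mouth_pts], axis=0
    )
    prob = (
        cfg.mangrove_fraction
        * np.exp(-pd_shore / (3.5 * px))
        * (0.45 + 0.55 * np.exp(-d_mouth / (10.0 * cell)))
    )
    # suppress mangroves along the developed stretch
    dev_cells = set(map(tuple, np.array([rows[dev], cols[dev]]).T))
    cell_r = (wrow // sub).astype(int)
    cell_c = (wcol // sub).astype(int)
    is_dev_px = np.fromiter(
        ((r, c) in dev_cells for r, c in zip(cell_r, cell_c)),
        dtype=bool, count=len(wrow),
    )
    prob = np.where(is_dev_px, prob * 0.05, prob)
    # patchy uniform noise: smooth white noise, then map back to uniform
    # quantiles so the threshold retains its marginal meaning
    noise_grid = ndimage.gaussian_filter(rng.random((H, W)), sigma=1.0)
    u = noise_grid[wrow, wcol]
    from scipy.stats import rankdata

    u = rankdata(u) / (len(u) + 1.0)
    mang = np.zeros((H, W), dtype=bool)
    mang[wrow, wcol] = u < prob
    mangrove = rmod.Raster(mang.astype(np.uint8), x0=0.0, y0=ny * cell, cell=px)

    # --- habitat rasters through the raster toolchain ------------------
    buffer_m = cfg.shore_buffer_m if cfg.shore_buffer_m is not None else 3.0 * px
    mdist = rmod.mangrove_distance_to_shore(mangrove, shoreline, buffer_m=buffer_m)
    mfocal = rmod.mangrove_focal_sum(mangrove)

    microgrids = [cell_boxes[(r, c)] for r, c in zip(rows, cols)]
    zonal = rmod.zonal_stats(microgrids, mdist, mfocal)

    cells = pd.DataFrame({
        "microgrid_id": np.arange(len(rows)),
        "row": rows, "col": cols, "x": xs, "y": ys,
        "river": river_id.astype(str),
        "dist_to_rm_m": dist_rm,
        "depth_min_m": base,
        "developed_sl": dev.astype(int),
        "min_mdts": zonal["min_mdts"].to_numpy(),
        "sum_mnn": zonal["sum_mnn"].to_numpy(),
    })
    return EstuaryScene(cfg, cells, depth, mangrove, mdist, mfocal,
                        shoreline, water_poly, microgrids)
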