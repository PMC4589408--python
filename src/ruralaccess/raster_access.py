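"""Raster travel-time engine.

Builds an anisotropic move-cost graph over the elevation grid (8 or 16
neighbours), where the slope *along the move* drives the walking-speed rule
and the Horn slope of each cell drives the slope-class friction coefficient,
then accumulates exact least-time surfaces from facility source cells with a
multi-source Dijkstra (scipy's sparse shortest path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .geodata_io import FacilityTable, LandUseGrid, TerrainModel
from .speed_model import (
    FrictionTable,
    SpeedRule,
    walking_pace_min_per_km,
)

__all__ = [
    "CostContext",
    "TravelTimeSurface",
    "slope_grid",
    "move_time",
    "accumulate",
    "band",
    "NEIGHBOR_OFFSETS_8",
    "NEIGHBOR_OFFSETS_16",
]

# orthogonal + diagonal moves
NEIGHBOR_OFFSETS_8 = tuple(
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
)
# queen moves plus knight moves
NEIGHBOR_OFFSETS_16 = NEIGHBOR_OFFSETS_8 + (
    (-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1),
)

BEYOND_RANGE = -1  # band index for cells beyond the maximum time / unreachable


def slope_grid(terrain: TerrainModel) -> np.ndarray:
    """Per-cell slope in percent from the Horn 3x3 finite-difference stencil.

    Masked cells contribute their nearest valid neighbour's elevation to the
    stencil (edge replication also applies at the grid border); the returned
    array is NaN at masked cells.
    """
    ny, nx = terrain.shape
    if ny < 2 or nx < 2:
        raise ValueError("need at least a 2x2 grid to compute slope")
    z = np.array(terrain.data, dtype=float)
    mask = terrain.nodata_mask
    if mask.any():
        # fill masked cells with nearest valid value so the stencil stays finite
        from scipy.ndimage import distance_transform_edt

        idx = distance_transform_edt(mask, return_distances=False,
                                     return_indices=True)
        z = z[tuple(idx)]
    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2]; f = zp[1:-1, 2:]
    g = zp[2:, :-2]; h = zp[2:, 1:-1]; i = zp[2:, 2:]
    cs = terrain.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    slope = np.hypot(dzdx, dzdy) * 100.0
    slope[mask] = np.nan
    return slope


@dataclass
class CostContext:
    """Everything needed to price a move between two grid cells."""

    terrain: TerrainModel
    landuse: LandUseGrid
    rule: SpeedRule = field(default_factory=SpeedRule)
    friction: FrictionTable = field(default_factory=FrictionTable)
    connectivity: int = 16

    def __post_init__(self) -> None:
        if not self.terrain.same_geometry(self.landuse):
            raise ValueError("terrain and land-use grids must be aligned")
        if self.connectivity not in (8, 16):
            raise ValueError("connectivity must be 8 or 16")
        self._slope_pct = slope_grid(self.terrain)
        self._cell_coeff = self._per_cell_coefficients()

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        return (NEIGHBOR_OFFSETS_16 if self.connectivity == 16
                else NEIGHBOR_OFFSETS_8)

    @property
    def passable(self) -> np.ndarray:
        return ~(self.terrain.nodata_mask | self.landuse.barrier_mask)

    def _per_cell_coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """(slope-class coeff, land-use coeff) per cell; NaN where impassable."""
        edges = np.array(self.friction.slope_edges)
        coeffs = np.array(self.friction.slope_coeffs)
        cls = np.searchsorted(edges, np.nan_to_num(self._slope_pct, nan=0.0),
                              side="right")
        slope_c = coeffs[cls].astype(float)
        season = self.landuse.season
        lu_table = self.friction.landuse_coeffs[season]
        lu_c = np.full(self.landuse.shape, np.nan)
        from .geodata_io import LANDUSE_CODES

        for name, code in LANDUSE_CODES.items():
            if name == "barrier":
                continue
            lu_c[self.landuse.data == code] = lu_table[name]
        bad = ~self.passable
        slope_c[bad] = np.nan
        lu_c[bad] = np.nan
        return slope_c, lu_c


def move_time(ctx: CostContext, from_cell: tuple[int, int],
              to_cell: tuple[int, int]) -> float:
    """Minutes to move between two adjacent cells (anisotropic)."""
    di = to_cell[0] - from_cell[0]
    dj = to_cell[1] - from_cell[1]
    if (di, dj) not in ctx.offsets:
        raise ValueError(f"cells not adjacent under {ctx.connectivity}-connectivity")
    if not (ctx.passable[from_cell] and ctx.passable[to_cell]):
        from .speed_model import Impassable

        raise Impassable(f"move {from_cell} -> {to_cell} crosses a barrier")
    dist = float(np.hypot(di, dj)) * ctx.terrain.cell_size
    dz = float(ctx.terrain.data[to_cell] - ctx.terrain.data[from_cell])
    pace = walking_pace_min_per_km(dz / dist, ctx.rule)
    sc, lc = ctx._cell_coeff
    slope_c = 0.5 * (sc[from_cell] + sc[to_cell])
    lu_c = 0.5 * (lc[from_cell] + lc[to_cell])
    return (dist / 1000.0) * pace * slope_c * lu_c


@dataclass
class TravelTimeSurface:
    """Minutes-to-nearest-source per cell (inf where unreachable)."""

    minutes: np.ndarray
    terrain: TerrainModel
    source_ids: tuple = ()
    mode: str = "pedestrian"
    band_width: float = 20.0

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        if self.minutes.shape != self.terrain.shape:
            raise ValueError("surface shape must match terrain")

    def as_grid(self):
        from .geodata_io import Grid

        return Grid(self.minutes, self.terrain.cell_size, self.terrain.origin,
                    self.terrain.crs_id,
                    nodata_mask=~np.isfinite(self.minutes))


def _move_graph(ctx: CostContext):
    """Directed sparse adjacency of per-move minutes over passable cells."""
    ny, nx = ctx.terrain.shape
    n = ny * nx
    z = ctx.terrain.data
    sc, lc = ctx._cell_coeff
    passable = ctx.passable
    rows, cols, vals = [], [], []
    cs = ctx.terrain.cell_size
    rule = ctx.rule
    base = 60.0 / rule.basal_speed_kmh
    tan_lo = np.tan(np.radians(rule.bonus_min_deg))
    tan_hi = np.tan(np.radians(rule.bonus_max_deg))
    for di, dj in ctx.offsets:
        src = np.s_[max(0, -di): ny - max(0, di), max(0, -dj): nx - max(0, dj)]
        dst = np.s_[max(0, di): ny - max(0, -di), max(0, dj): nx - max(0, -dj)]
        ok = passable[src] & passable[dst]
        if not ok.any():
            continue
        dist = float(np.hypot(di, dj)) * cs
        slope = (z[dst] - z[src]) / dist
        # vectorised walking pace (min per km) under the slope rule
        vert = np.abs(slope) * 1000.0
        pace = np.full(slope.shape, base)
        up = slope > 0
        pace[up] = base + rule.ascent_penalty_min_per_m * vert[up]
        down = slope < 0
        bonus = down & (np.abs(slope) > tan_lo) & (np.abs(slope) <= tan_hi)
        steep = down & (np.abs(slope) > tan_hi)
        pace[bonus] = base - rule.descent_bonus_min_per_m * vert[bonus]
        pace[steep] = base + rule.steep_descent_penalty_min_per_m * vert[steep]
        coeff = 0.25 * (sc[src] + sc[dst]) * (lc[src] + lc[dst])  # mean*mean
        t = (dist / 1000.0) * pace * coeff
        ii, jj = np.nonzero(ok)
        r = (ii + max(0, -di)) * nx + (jj + max(0, -dj))
        c = (ii + max(0, di)) * nx + (jj + max(0, dj))
        rows.append(r)
        cols.append(c)
        vals.append(t[ok])
    rows = np.concatenate(rows) if rows else np.empty(0, int)
    cols = np.concatenate(cols) if cols else np.empty(0, int)
    vals = np.concatenate(vals) if vals else np.empty(0, float)
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _source_cells(ctx: CostContext, sources) -> tuple[list[int], tuple]:
    """Resolve sources (FacilityTable or (row, col) list) to flat indices."""
    ny, nx = ctx.terrain.shape
    if isinstance(sources, FacilityTable):
        cells, ids = [], []
        for _, row in sources.frame.iterrows():
            r, c = ctx.terrain.cell_of(row["x"], row["y"])
            cells.append((r, c))
            ids.append(row["id"])
    else:
        cells = [tuple(c) for c in sources]
        ids = list(range(len(cells)))
    flat, kept = [], []
    for (r, c), fid in zip(cells, ids):
        if ctx.passable[r, c]:
            flat.append(r * nx + c)
            kept.append(fid)
    if not flat:
        raise ValueError("all sources fall on masked or barrier cells")
    return flat, tuple(kept)


def accumulate(ctx: CostContext, sources, mode: str = "pedestrian",
               band_width: float = 20.0) -> TravelTimeSurface:
    """Least travel time from the nearest source to every cell.

    ``sources`` is a FacilityTable (coordinates mapped to their cells) or an
    iterable of (row, col) pairs.  Exact shortest-path semantics.
    """
    flat, ids = _source_cells(ctx, sources)
    graph = _move_graph(ctx)
    # travel time *to* a facility: run Dijkstra from sources over the
    # transposed graph so direction-dependent costs are honoured
    dist = dijkstra(graph.T, directed=True, indices=flat, min_only=True)
    minutes = dist.reshape(ctx.terrain.shape)
    minutes[~ctx.passable] = np.inf
    return TravelTimeSurface(minutes, ctx.terrain, source_ids=ids, mode=mode,
                             band_width=band_width)


def band(surface_minutes, width: float, max_minutes: float) -> np.ndarray:
    """Band index per cell: band k covers ((k-1)*width, k*width]; sources
    (0 min) are band 1; times beyond ``max_minutes`` get BEYOND_RANGE."""
    if width <= 0:
        raise ValueError("band width must be positive")
    nbands = max_minutes / width
    if abs(nbands - round(nbands)) > 1e-9:
        raise ValueError("max must be a multiple of width")
    t = np.asarray(getattr(surface_minutes, "minutes", surface_minutes),
                   dtype=float)
    with np.errstate(invalid="ignore"):
        idx = np.ceil(t / width).astype(float)
    idx = np.maximum(idx, 1.0)
    out = np.where(np.isfinite(t) & (t <= max_minutes + 1e-12), idx,
                   float(BEYOND_RANGE))
    return out.astype(int)
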