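"""Virtual-network travel-time engine.

A triangular lattice of short edges (the hexagonal tiling's cell perimeters
plus their centre spokes collapse to exactly this lattice) stands in for
missing footpath data; mapped roads are densified and merged in.  Every edge
carries a travel time per direction from the slope rule, and shortest-path
service areas are computed for pedestrian or multimodal (walk + ride on
motorable roads) travel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .geodata_io import FacilityTable, LandUseGrid, RoadNetwork, TerrainModel
from .speed_model import (
    MOTORIZED_CLASSES,
    FrictionTable,
    RoadSpeedTable,
    SpeedRule,
    walking_pace_min_per_km,
)

__all__ = [
    "MeshGraph",
    "ServiceArea",
    "generate_mesh",
    "merge_roads",
    "weight_edges",
    "shortest_times",
    "service_area",
    "node_bands",
]

BEYOND_RANGE = -1


@dataclass
class MeshGraph:
    """Node/edge graph of the virtual mesh plus merged road segments.

    ``edges`` columns: (u, v) int node ids. Parallel arrays hold lengths,
    kinds ("mesh"/"road"), road classes ("" for mesh edges) and, once
    :func:`weight_edges` has run, per-direction pedestrian minutes and
    symmetric vehicular minutes (NaN when not motorable).
    """

    xy: np.ndarray
    elevation: np.ndarray
    edges: np.ndarray
    length: np.ndarray
    kind: np.ndarray
    road_class: np.ndarray
    side: float
    time_fwd: np.ndarray | None = None
    time_rev: np.ndarray | None = None
    time_vehicle: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        if len(self.elevation) != len(self.xy):
            raise ValueError("one elevation per node required")
        if self.edges.size and self.edges.max() >= len(self.xy):
            raise ValueError("edge endpoint out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.xy)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def is_weighted(self) -> bool:
        return self.time_fwd is not None

    def nearest_node(self, x: float, y: float) -> tuple[int, float]:
        tree = cKDTree(self.xy)
        d, i = tree.query([x, y])
        return int(i), float(d)

    def to_geojson(self, path) -> None:
        feats = []
        for k, (u, v) in enumerate(self.edges):
            props = {
                "kind": str(self.kind[k]),
                "road_class": str(self.road_class[k]),
                "length_m": float(self.length[k]),
            }
            if self.is_weighted():
                props["time_fwd_min"] = float(self.time_fwd[k])
                props["time_rev_min"] = float(self.time_rev[k])
                tv = float(self.time_vehicle[k])
                props["time_vehicle_min"] = None if math.isnan(tv) else tv
            feats.append({
                "type": "Feature",
                "properties": props,
                "geometry": {"type": "LineString", "coordinates": [
                    [float(self.xy[u, 0]), float(self.xy[u, 1])],
                    [float(self.xy[v, 0]), float(self.xy[v, 1])],
                ]},
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    def edge_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "u": self.edges[:, 0], "v": self.edges[:, 1],
            "length_m": self.length, "kind": self.kind,
            "road_class": self.road_class,
        })
        if self.is_weighted():
            df["time_fwd_min"] = self.time_fwd
            df["time_rev_min"] = self.time_rev
            df["time_vehicle_min"] = self.time_vehicle
        df.to_csv(path, index=False)


def _sample_terrain(terrain: TerrainModel, xy: np.ndarray) -> np.ndarray:
    """Bilinear elevation sample at projected points (clamped to the grid)."""
    x0, y0 = terrain.origin
    cs = terrain.cell_size
    ny, nx = terrain.shape
    cx = np.clip((xy[:, 0] - x0) / cs - 0.5, 0, nx - 1)
    cy = np.clip((y0 - xy[:, 1]) / cs - 0.5, 0, ny - 1)
    i0 = np.floor(cy).astype(int); j0 = np.floor(cx).astype(int)
    i1 = np.minimum(i0 + 1, ny - 1); j1 = np.minimum(j0 + 1, nx - 1)
    fy = cy - i0; fx = cx - j0
    z = terrain.data
    return ((z[i0, j0] * (1 - fx) + z[i0, j1] * fx) * (1 - fy)
            + (z[i1, j0] * (1 - fx) + z[i1, j1] * fx) * fy)


def _inside_cells(grid, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) of each point, clipped to the grid."""
    x0, y0 = grid.origin
    cs = grid.cell_size
    ny, nx = grid.shape
    col = np.clip(np.floor((xy[:, 0] - x0) / cs).astype(int), 0, nx - 1)
    row = np.clip(np.floor((y0 - xy[:, 1]) / cs).astype(int), 0, ny - 1)
    return row, col


def generate_mesh(extent: tuple[float, float, float, float], side: float,
                  terrain: TerrainModel, landuse: LandUseGrid | None = None,
                  ) -> MeshGraph:
    """Triangular lattice with node spacing ``side`` clipped to the extent.

    The lattice is the union of a hexagonal tiling's perimeter edges and the
    centre-to-vertex spokes of each hexagon, so every edge has length
    ``side``.  Nodes on barrier cells are dropped together with their edges.
    """
    if side <= 0:
        raise ValueError("mesh side must be positive")
    xmin, ymin, xmax, ymax = extent
    dy = side * math.sqrt(3) / 2
    n_rows = int(math.floor((ymax - ymin) / dy)) + 1
    n_cols = int(math.floor((xmax - xmin) / side)) + 1
    if n_rows < 2 or n_cols < 2:
        raise ValueError("extent smaller than one mesh cell")
    pts = []
    index = {}
    for r in range(n_rows):
        xoff = 0.5 * side if r % 2 else 0.0
        y = ymin + r * dy
        for c in range(n_cols):
            x = xmin + xoff + c * side
            if x > xmax + 1e-9:
                continue
            index[(r, c)] = len(pts)
            pts.append((x, y))
    xy = np.array(pts)
    edges = []
    for (r, c), i in index.items():
        # right neighbour
        j = index.get((r, c + 1))
        if j is not None:
            edges.append((i, j))
        # two neighbours in the row above
        if r % 2:
            below = ((r + 1, c), (r + 1, c + 1))
        else:
            below = ((r + 1, c - 1), (r + 1, c))
        for key in below:
            j = index.get(key)
            if j is not None:
                edges.append((i, j))
    edges = np.array(edges, dtype=int)
    elev = _sample_terrain(terrain, xy)

    keep = np.ones(len(xy), dtype=bool)
    if landuse is not None:
        row, col = _inside_cells(landuse, xy)
        keep &= ~landuse.barrier_mask[row, col]
    row, col = _inside_cells(terrain, xy)
    keep &= ~terrain.nodata_mask[row, col]
    if not keep.any():
        raise ValueError("no mesh nodes remain (all-barrier extent)")
    remap = -np.ones(len(xy), dtype=int)
    remap[keep] = np.arange(keep.sum())
    xy = xy[keep]
    elev = elev[keep]
    if len(edges):
        e = remap[edges]
        e = e[(e >= 0).all(axis=1)]
    else:
        e = np.empty((0, 2), dtype=int)
    length = np.hypot(*(xy[e[:, 0]] - xy[e[:, 1]]).T) if len(e) else np.empty(0)
    return MeshGraph(
        xy=xy, elevation=elev, edges=e, length=length,
        kind=np.array(["mesh"] * len(e)),
        road_class=np.array([""] * len(e), dtype=object),
        side=side,
    )


def _densify(seg: np.ndarray, max_len: float) -> np.ndarray:
    """Insert vertices so no segment piece exceeds ``max_len``."""
    out = [seg[0]]
    for a, b in zip(seg[:-1], seg[1:]):
        d = math.hypot(*(b - a))
        n = max(1, int(math.ceil(d / max_len)))
        for k in range(1, n + 1):
            out.append(a + (b - a) * (k / n))
    return np.array(out)


def merge_roads(graph: MeshGraph, roads: RoadNetwork, terrain: TerrainModel,
                snap_tolerance: float = 20.0) -> MeshGraph:
    """Densify road polylines and weld them into the mesh.

    Road vertices within ``snap_tolerance`` of an existing node reuse it;
    other vertices become new nodes linked to their nearest mesh nodes so the
    walker can step on and off the road anywhere.  Road edges survive barrier
    water (mapped roads imply bridges or ferries).
    """
    if len(roads) == 0:
        return graph
    xy = [tuple(p) for p in graph.xy]
    elev = list(graph.elevation)
    tree = cKDTree(graph.xy)
    new_edges = list(map(tuple, graph.edges))
    new_len = list(graph.length)
    new_kind = list(graph.kind)
    new_cls = list(graph.road_class)
    link_edges = []  # new-node-to-mesh connector edges (kind mesh)

    n0 = len(xy)
    for seg, cls in zip(roads.segments, roads.road_classes):
        dense = _densify(np.asarray(seg, dtype=float), graph.side)
        ids = []
        for p in dense:
            d, i = tree.query(p)
            if d <= snap_tolerance:
                ids.append(int(i))
                continue
            idx = len(xy)
            xy.append((float(p[0]), float(p[1])))
            elev.append(float(_sample_terrain(terrain, p[None, :])[0]))
            ids.append(idx)
            # connect the inserted node to the surrounding mesh cell
            dists, near = tree.query(p, k=3)
            for dd, nn in zip(np.atleast_1d(dists), np.atleast_1d(near)):
                if np.isfinite(dd) and dd <= graph.side * 1.05:
                    link_edges.append((idx, int(nn), float(dd)))
        for u, v in zip(ids[:-1], ids[1:]):
            if u == v:
                continue
            d = math.hypot(xy[u][0] - xy[v][0], xy[u][1] - xy[v][1])
            new_edges.append((u, v))
            new_len.append(d)
            new_kind.append("road")
            new_cls.append(cls)

    for u, v, d in link_edges:
        new_edges.append((u, v))
        new_len.append(d)
        new_kind.append("mesh")
        new_cls.append("")

    return MeshGraph(
        xy=np.array(xy), elevation=np.array(elev),
        edges=np.array(new_edges, dtype=int), length=np.array(new_len),
        kind=np.array(new_kind), road_class=np.array(new_cls, dtype=object),
        side=graph.side,
    )


def weight_edges(graph: MeshGraph, rule: SpeedRule | None = None,
                 friction: FrictionTable | None = None,
                 roads: RoadSpeedTable | None = None,
                 landuse: LandUseGrid | None = None) -> MeshGraph:
    """Attach per-direction pedestrian minutes and vehicular minutes.

    Pedestrian time applies the slope rule to the edge's signed slope in each
    direction, the slope-class coefficient from the (unsigned) edge slope and
    the land-use coefficient sampled at the edge midpoint.  Vehicular time is
    symmetric, length over the class speed, only on motorable road classes.
    """
    rule = rule or SpeedRule()
    friction = friction or FrictionTable()
    roads = roads or RoadSpeedTable()
    if not np.all(np.isfinite(graph.elevation)):
        raise ValueError("node elevations must be populated before weighting")
    e = graph.edges
    dz = graph.elevation[e[:, 1]] - graph.elevation[e[:, 0]]
    length = np.maximum(graph.length, 1e-9)
    slope = dz / length

    lu_coeff = np.ones(len(e))
    if landuse is not None:
        mid = 0.5 * (graph.xy[e[:, 0]] + graph.xy[e[:, 1]])
        row, col = _inside_cells(landuse, mid)
        table = friction.landuse_coeffs[landuse.season]
        from .geodata_io import LANDUSE_CODES

        codes = landuse.data[row, col]
        for name, code in LANDUSE_CODES.items():
            if name == "barrier":
                # roads cross water; walkers use the roadway surface
                lu_coeff[codes == code] = table["open"]
            else:
                lu_coeff[codes == code] = table[name]

    slope_coeff = np.array([friction.slope_coeff(abs(s) * 100) for s in slope])
    pace_fwd = np.array([walking_pace_min_per_km(s, rule) for s in slope])
    pace_rev = np.array([walking_pace_min_per_km(-s, rule) for s in slope])
    km = length / 1000.0
    t_fwd = km * pace_fwd * slope_coeff * lu_coeff
    t_rev = km * pace_rev * slope_coeff * lu_coeff

    t_veh = np.full(len(e), np.nan)
    is_road = graph.kind == "road"
    for cls in MOTORIZED_CLASSES:
        sel = is_road & (graph.road_class == cls)
        if sel.any():
            t_veh[sel] = km[sel] / roads.speed(cls) * 60.0

    out = MeshGraph(
        xy=graph.xy, elevation=graph.elevation, edges=graph.edges,
        length=graph.length, kind=graph.kind, road_class=graph.road_class,
        side=graph.side, time_fwd=t_fwd, time_rev=t_rev, time_vehicle=t_veh,
    )
    return out


def _sparse_times(graph: MeshGraph, mode: str):
    """Directed sparse matrix of per-edge minutes for the given mode."""
    if not graph.is_weighted():
        raise ValueError("weight_edges must run first")
    if mode not in ("pedestrian", "multimodal"):
        raise ValueError("mode must be pedestrian or multimodal")
    fwd = graph.time_fwd.copy()
    rev = graph.time_rev.copy()
    if mode == "multimodal":
        veh = graph.time_vehicle
        ok = np.isfinite(veh)
        fwd[ok] = np.minimum(fwd[ok], veh[ok])
        rev[ok] = np.minimum(rev[ok], veh[ok])
    n = graph.n_nodes
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    rows = np.concatenate([u, v])
    cols = np.concatenate([v, u])
    vals = np.concatenate([fwd, rev])
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def facility_nodes(graph: MeshGraph, facilities: FacilityTable) -> dict:
    """Map facility ids to their nearest graph node; error beyond one side."""
    tree = cKDTree(graph.xy)
    out = {}
    for _, row in facilities.frame.iterrows():
        d, i = tree.query([row["x"], row["y"]])
        if d > graph.side:
            raise ValueError(
                f"facility {row['id']} is {d:.0f} m from the nearest node "
                f"(> mesh side {graph.side:.0f} m)")
        out[row["id"]] = int(i)
    return out


def shortest_times(graph: MeshGraph, facilities, mode: str = "pedestrian",
                   ) -> np.ndarray:
    """Per-node minutes to the nearest facility (direction-correct)."""
    if isinstance(facilities, FacilityTable):
        nodes = list(facility_nodes(graph, facilities).values())
    else:
        nodes = [int(f) for f in facilities]
    if not nodes:
        raise ValueError("need at least one facility")
    mat = _sparse_times(graph, mode)
    # time *towards* facilities: expand over reversed edges
    return dijkstra(mat.T, directed=True, indices=nodes, min_only=True)


@dataclass
class ServiceArea:
    """Travel-time bands around one facility."""

    facility_id: object
    node_minutes: np.ndarray
    band_width: float
    max_minutes: float
    bands: dict = field(default_factory=dict)  # band index -> node id array

    def band_nodes(self, k: int) -> np.ndarray:
        return self.bands.get(k, np.empty(0, dtype=int))

    def nodes_within(self, minutes: float) -> np.ndarray:
        return np.nonzero(self.node_minutes <= minutes + 1e-12)[0]


def node_bands(minutes: np.ndarray, width: float, max_minutes: float,
               ) -> np.ndarray:
    """Same banding convention as the raster engine, over node times."""
    from .raster_access import band as _band

    return _band(np.asarray(minutes), width, max_minutes)


def service_area(graph: MeshGraph, facility, band_width: float = 20.0,
                 max_minutes: float = 120.0, mode: str = "pedestrian",
                 ) -> ServiceArea:
    """Band partition of all nodes around a single facility."""
    if isinstance(facility, FacilityTable):
        fid, node = next(iter(facility_nodes(graph, facility).items()))
    else:
        fid, node = facility, int(facility)
    minutes = shortest_times(graph, [node], mode=mode)
    idx = node_bands(minutes, band_width, max_minutes)
    bands = {int(k): np.nonzero(idx == k)[0]
             for k in np.unique(idx) if k != BEYOND_RANGE}
    return ServiceArea(fid, minutes, band_width, max_minutes, bands)


def n_components(graph: MeshGraph) -> int:
    n = graph.n_nodes
    if graph.n_edges == 0:
        return n
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    mat = coo_matrix((np.ones(len(u)), (u, v)), shape=(n, n))
    return connected_components(mat, directed=False)[0]
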