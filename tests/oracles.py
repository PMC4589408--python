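"""Independent brute-force oracles for the travel-time engines.

Everything here is deliberately written from the published rule statements
(scalar arithmetic, heapq Dijkstra) without touching the package's vectorised
code paths, so the two routes can be compared.
"""

from __future__ import annotations

import heapq
import math

import numpy as np

SLOPE_CLASS = [(20, 0.98), (40, 1.00), (60, 1.20), (80, 1.04), (100, 1.06)]
SLOPE_TAIL = 1.08
LANDUSE = {
    "dry": {0: 0.95, 1: 1.00, 2: 1.05},
    "wet": {0: 1.00, 1: 1.05, 2: 1.10},
}
BARRIER = 3


def pace_min_per_km(slope: float) -> float:
    """Langmuir rule: 4 km/h basal, +0.1 min/m up, -0.03 min/m down between
    5 and 12 degrees, +0.03 min/m down when steeper."""
    base = 15.0
    metres = abs(slope) * 1000.0
    if slope > 0:
        return base + 0.1 * metres
    if slope < 0:
        deg = math.degrees(math.atan(abs(slope)))
        if deg <= 5.0:
            return base
        if deg <= 12.0:
            return base - 0.03 * metres
        return base + 0.03 * metres
    return base


def slope_class_coeff(slope_pct: float) -> float:
    for edge, coeff in SLOPE_CLASS:
        if abs(slope_pct) < edge:
            return coeff
    return SLOPE_TAIL


def horn_slope_pct(z: np.ndarray, cell: float) -> np.ndarray:
    ny, nx = z.shape
    out = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            def at(r, c):
                return z[min(max(r, 0), ny - 1), min(max(c, 0), nx - 1)]

            a, b, c_ = at(i - 1, j - 1), at(i - 1, j), at(i - 1, j + 1)
            d, f = at(i, j - 1), at(i, j + 1)
            g, h, ii = at(i + 1, j - 1), at(i + 1, j), at(i + 1, j + 1)
            dzdx = ((c_ + 2 * f + ii) - (a + 2 * d + g)) / (8 * cell)
            dzdy = ((g + 2 * h + ii) - (a + 2 * b + c_)) / (8 * cell)
            out[i, j] = math.hypot(dzdx, dzdy) * 100
    return out


def raster_oracle(z: np.ndarray, landuse: np.ndarray, cell: float,
                  sources, season: str = "dry", connectivity: int = 16,
                  ) -> np.ndarray:
    """Minutes to the nearest source per cell by heapq Dijkstra, pricing each
    move with scalar arithmetic straight from the published tables."""
    ny, nx = z.shape
    slope_pct = horn_slope_pct(z, cell)
    offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
               if (di, dj) != (0, 0)]
    if connectivity == 16:
        offsets += [(-2, -1), (-2, 1), (-1, -2), (-1, 2),
                    (1, -2), (1, 2), (2, -1), (2, 1)]
    passable = landuse != BARRIER
    lu = LANDUSE[season]

    def cell_coeffs(i, j):
        return slope_class_coeff(slope_pct[i, j]), lu[int(landuse[i, j])]

    dist = np.full((ny, nx), np.inf)
    heap = []
    for (si, sj) in sources:
        if passable[si, sj]:
            dist[si, sj] = 0.0
            heapq.heappush(heap, (0.0, si, sj))
    while heap:
        t, i, j = heapq.heappop(heap)
        if t > dist[i, j]:
            continue
        for di, dj in offsets:
            ni, nj = i + di, j + dj
            if not (0 <= ni < ny and 0 <= nj < nx) or not passable[ni, nj]:
                continue
            d = math.hypot(di, dj) * cell
            slope = (z[ni, nj] - z[i, j]) / d
            sc1, lc1 = cell_coeffs(i, j)
            sc2, lc2 = cell_coeffs(ni, nj)
            # time of the move *away* from the source means the traveller is
            # walking towards the facility; the engine accumulates time
            # towards facilities, so reverse the slope sign
            move = (d / 1000.0) * pace_min_per_km(-slope) \
                * 0.5 * (sc1 + sc2) * 0.5 * (lc1 + lc2)
            nt = t + move
            if nt < dist[ni, nj] - 1e-15:
                dist[ni, nj] = nt
                heapq.heappush(heap, (nt, ni, nj))
    dist[~passable] = np.inf
    return dist


def graph_oracle(n_nodes: int, edges, time_fwd, time_rev, sources,
                 ) -> np.ndarray:
    """Multi-source Dijkstra over an explicit edge list, travelling towards
    the sources (so each edge is relaxed with its direction-correct time)."""
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n_nodes)]
    for (u, v), tf, tr in zip(edges, time_fwd, time_rev):
        # walking u->v costs tf; from a source's viewpoint we expand outwards
        # over reversed edges, so arriving at u via v costs tf
        adj[v].append((u, tf))
        adj[u].append((v, tr))
    dist = [math.inf] * n_nodes
    heap = []
    for s in sources:
        dist[s] = 0.0
        heapq.heappush(heap, (0.0, s))
    while heap:
        t, u = heapq.heappop(heap)
        if t > dist[u]:
            continue
        for v, w in adj[u]:
            nt = t + w
            if nt < dist[v] - 1e-15:
                dist[v] = nt
                heapq.heappush(heap, (nt, v))
    return np.array(dist)
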