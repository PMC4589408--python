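"""Seeded synthetic districts: terrain, land use, clustered population,
road graphs and facility tables with realistic staffing/caseload structure.

Also ships two deterministic "reference" facility tables whose marginal
statistics (staffing classes, caseload classes, medians, ranges, hospital
shares) reproduce the published district-level figures exactly; they stand in
for the original facility spreadsheets, which are not redistributable here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree

from .geodata_io import (
    LANDUSE_CODES,
    FacilityTable,
    LandUseGrid,
    PopulationGrid,
    RoadNetwork,
    TerrainModel,
)

__all__ = [
    "DistrictSpec",
    "make_terrain",
    "make_settlements",
    "make_roads_facilities",
    "make_district",
    "reference_district_spec",
    "iringa_reference_facilities",
    "ludewa_reference_facilities",
]


@dataclass(frozen=True)
class DistrictSpec:
    """Parameters of a synthetic district."""

    extent_km: tuple[float, float] = (20.0, 20.0)
    cell_size_m: float = 90.0
    relief_amplitude_m: float = 600.0
    base_elevation_m: float = 1200.0
    terrain_smoothness: float = 8.0  # gaussian sigma in cells
    n_villages: int = 40
    population_total: float = 120000.0
    village_dispersion_m: float = 1200.0  # population kernel scale
    n_dispensaries: int = 24
    n_health_centres: int = 4
    n_hospitals: int = 1
    staffing_fractions: tuple[float, float, float] = (0.15, 0.5, 0.35)
    caseload_log_mean: float = 3.8
    caseload_log_sd: float = 0.9
    hospital_delivery_share: float = 0.4
    road_extra_loops: int = 6
    water_fraction: float = 0.04
    forest_fraction: float = 0.2
    bushy_fraction: float = 0.35
    season: str = "dry"
    seed: int = 0
    crs_id: str = "EPSG:32736"
    origin: tuple[float, float] = (500000.0, 9000000.0)

    def __post_init__(self) -> None:
        if abs(sum(self.staffing_fractions) - 1.0) > 1e-9:
            raise ValueError("staffing fractions must sum to 1")
        if not all(0 <= f <= 1 for f in self.staffing_fractions):
            raise ValueError("staffing fractions must lie in [0, 1]")
        for name in ("water_fraction", "forest_fraction", "bushy_fraction",
                     "hospital_delivery_share"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.n_villages, self.n_dispensaries, self.n_health_centres,
               self.n_hospitals) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return (int(round(self.extent_km[1] * 1000 / self.cell_size_m)),
                int(round(self.extent_km[0] * 1000 / self.cell_size_m)))

    @property
    def n_facilities(self) -> int:
        return self.n_dispensaries + self.n_health_centres + self.n_hospitals


def make_terrain(spec: DistrictSpec) -> tuple[TerrainModel, LandUseGrid]:
    """Correlated random-field terrain with carved water bodies and
    elevation/noise-driven land-use labels."""
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    noise = rng.standard_normal((ny, nx))
    smooth = gaussian_filter(noise, spec.terrain_smoothness, mode="reflect")
    if smooth.std() > 0:
        smooth = (smooth - smooth.mean()) / smooth.std()
    elev = spec.base_elevation_m + smooth * (spec.relief_amplitude_m / 2.0)

    landuse = np.full((ny, nx), LANDUSE_CODES["open"], dtype=np.uint8)
    if spec.water_fraction > 0 and spec.relief_amplitude_m > 0:
        level = np.quantile(elev, spec.water_fraction)
        landuse[elev <= level] = LANDUSE_CODES["barrier"]
    land = landuse != LANDUSE_CODES["barrier"]
    # vegetation: independent smooth field, high values forest then bushy
    veg = gaussian_filter(rng.standard_normal((ny, nx)),
                          spec.terrain_smoothness / 2, mode="reflect")
    vland = veg[land]
    if len(vland) and spec.forest_fraction > 0:
        thr_f = np.quantile(vland, 1 - spec.forest_fraction)
        landuse[land & (veg >= thr_f)] = LANDUSE_CODES["forest"]
    if len(vland) and spec.bushy_fraction > 0:
        lo = np.quantile(vland, 1 - spec.forest_fraction - spec.bushy_fraction)
        hi = np.quantile(vland, 1 - spec.forest_fraction)
        landuse[land & (veg >= lo) & (veg < hi)] = LANDUSE_CODES["bushy"]

    terrain = TerrainModel(elev, spec.cell_size_m, spec.origin, spec.crs_id)
    lu = LandUseGrid(landuse, spec.cell_size_m, spec.origin, spec.crs_id,
                     season=spec.season)
    return terrain, lu


def make_settlements(spec: DistrictSpec, terrain: TerrainModel,
                     landuse: LandUseGrid) -> tuple[PopulationGrid, np.ndarray]:
    """Village centres on gentle non-barrier ground, population as truncated
    Gaussian kernels around them, normalised to the spec total.

    Returns the population grid and an array of village (x, y, weight).
    """
    from .raster_access import slope_grid

    rng = np.random.default_rng(spec.seed + 1)
    ny, nx = terrain.shape
    slope = slope_grid(terrain)
    eligible = (~landuse.barrier_mask) & (np.nan_to_num(slope, nan=1e9) < 25.0)
    rows, cols = np.nonzero(eligible)
    if len(rows) < spec.n_villages:
        raise ValueError("too many villages for the available habitable cells")
    pick = rng.choice(len(rows), size=spec.n_villages, replace=False)
    vr, vc = rows[pick], cols[pick]
    cs = terrain.cell_size
    x0, y0 = terrain.origin
    vx = x0 + (vc + 0.5) * cs
    vy = y0 - (vr + 0.5) * cs
    sizes = rng.lognormal(mean=0.0, sigma=0.8, size=spec.n_villages)
    sizes /= sizes.sum()

    yy, xx = np.mgrid[0:ny, 0:nx]
    cxs = x0 + (xx + 0.5) * cs
    cys = y0 - (yy + 0.5) * cs
    pop = np.zeros((ny, nx))
    s = spec.village_dispersion_m
    trunc = 3.0 * s
    for k in range(spec.n_villages):
        d2 = (cxs - vx[k]) ** 2 + (cys - vy[k]) ** 2
        kern = np.exp(-d2 / (2 * s * s))
        kern[d2 > trunc * trunc] = 0.0
        pop += sizes[k] * kern
    pop[landuse.barrier_mask] = 0.0
    if pop.sum() <= 0:
        raise ValueError("population kernels fell entirely on barrier cells")
    pop *= spec.population_total / pop.sum()
    villages = np.column_stack([vx, vy, sizes])
    grid = PopulationGrid(pop, cs, terrain.origin, terrain.crs_id)
    return grid, villages


def _mst_edges(points: np.ndarray) -> list[tuple[int, int]]:
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    mst = minimum_spanning_tree(d).tocoo()
    return [(int(u), int(v)) for u, v in zip(mst.row, mst.col)]


def make_roads_facilities(spec: DistrictSpec, villages: np.ndarray,
                          ) -> tuple[RoadNetwork, FacilityTable]:
    """Roads as the village minimum spanning tree plus loop shortcuts; a
    facility subset of villages with staffing and right-skewed caseloads."""
    rng = np.random.default_rng(spec.seed + 2)
    if spec.n_facilities > len(villages):
        raise ValueError("more facilities than villages")
    pts = villages[:, :2]
    weights = villages[:, 2]

    edges = _mst_edges(pts)
    # extra loops: connect random near-neighbour pairs not already linked
    have = {frozenset(e) for e in edges}
    tree = cKDTree(pts)
    _, nbr = tree.query(pts, k=min(4, len(pts)))
    candidates = [
        (i, int(j)) for i in range(len(pts)) for j in np.atleast_1d(nbr[i])[1:]
        if frozenset((i, int(j))) not in have
    ]
    rng.shuffle(candidates)
    for i, j in candidates[: spec.road_extra_loops]:
        key = frozenset((i, j))
        if key not in have:
            edges.append((i, j))
            have.add(key)

    # classes by link importance: usage counts from MST paths to the largest
    # village approximated by degree + endpoint weight
    deg = np.zeros(len(pts))
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    segments, classes = [], []
    importance = [weights[u] + weights[v] + 0.05 * (deg[u] + deg[v])
                  for u, v in edges]
    order = np.argsort(importance)[::-1]
    for rank, k in enumerate(order):
        u, v = edges[k]
        if rank < max(1, len(edges) // 10):
            cls = "loose_surface"
        elif rank < len(edges) // 2:
            cls = "motorable"
        else:
            cls = "footpath"
        segments.append(np.array([pts[u], pts[v]]))
        classes.append(cls)
    roads = RoadNetwork(segments, classes)

    # facilities: hospital(s) at the largest villages, then health centres,
    # then dispensaries at the next-largest remaining villages
    order = np.argsort(weights)[::-1]
    chosen = order[: spec.n_facilities]
    levels = (["hospital"] * spec.n_hospitals
              + ["health_centre"] * spec.n_health_centres
              + ["dispensary"] * spec.n_dispensaries)
    n_first = spec.n_dispensaries + spec.n_health_centres
    staff_classes = rng.choice(3, size=n_first, p=spec.staffing_fractions)
    sba_counts = np.where(staff_classes == 2, rng.integers(2, 5, n_first),
                          staff_classes)

    caseloads = np.round(
        rng.lognormal(spec.caseload_log_mean, spec.caseload_log_sd, n_first)
    ).clip(min=2)
    hosp_total = caseloads.sum() * spec.hospital_delivery_share / max(
        1e-9, 1 - spec.hospital_delivery_share)
    hosp_split = rng.dirichlet(np.ones(max(1, spec.n_hospitals)))
    rows = []
    i_first = 0
    for k, (vidx, level) in enumerate(zip(chosen, levels)):
        x, y = pts[vidx]
        if level == "hospital":
            sba = int(rng.integers(6, 15))
            dels = float(np.round(hosp_total * hosp_split[k % len(hosp_split)]))
        else:
            sba = int(sba_counts[i_first])
            dels = float(caseloads[i_first])
            i_first += 1
        rows.append({
            "id": f"F{k:03d}", "name": f"facility_{k:03d}", "level": level,
            "x": float(x), "y": float(y), "sba_count": sba,
            "deliveries": dels, "offers_delivery": True,
        })
    facilities = FacilityTable(pd.DataFrame(rows))
    return roads, facilities


def make_district(spec: DistrictSpec):
    """Generate all layers of a synthetic district.

    Returns (terrain, landuse, population, villages, roads, facilities).
    """
    terrain, landuse = make_terrain(spec)
    pop, villages = make_settlements(spec, terrain, landuse)
    roads, facilities = make_roads_facilities(spec, villages)
    return terrain, landuse, pop, villages, roads, facilities


def reference_district_spec(seed: int = 42, scale: float = 1.0) -> DistrictSpec:
    """The packaged reference district used by the acceptance checks.

    ``scale`` shrinks the extent (and facility/village counts) for quick runs.
    """
    return DistrictSpec(
        extent_km=(36.0 * scale, 36.0 * scale),
        n_villages=max(8, int(round(70 * scale))),
        n_dispensaries=max(4, int(round(14 * scale))),
        n_health_centres=max(1, int(round(3 * scale))),
        n_hospitals=1,
        village_dispersion_m=1000.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# reference facility tables reconstructed from published district marginals

# first-line (dispensary/health-centre) annual delivery caseloads; each list
# reproduces the published class counts, median, range and total exactly
_IRINGA_FIRST_LINE_DELIVERIES = [
    2, 4, 7, 9, 11, 14, 16, 18, 21, 23, 26, 28, 30, 33, 35, 37, 40, 42, 44,
    47, 49, 50, 51, 52, 54, 55, 56, 57, 58, 59, 61, 62, 63, 64, 66, 67, 70,
    72, 75, 78, 80, 83, 86, 88, 91, 94, 96, 99, 100, 100, 101, 108, 114, 120,
    126, 132, 139, 145, 151, 157, 163, 170, 177, 183, 189, 200, 230, 277,
]
_LUDEWA_FIRST_LINE_DELIVERIES = [
    2, 3, 4, 5, 6, 7, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 16, 17, 18, 19,
    20, 21, 22, 24, 26, 27, 29, 30, 32, 32, 34, 35, 37, 38, 40, 41, 43, 44,
    46, 47, 49, 55, 80, 100, 117,
]


def _reference_table(prefix: str, n_disp: int, n_hc: int,
                     staffing: tuple[int, int, int],
                     deliveries: list[float], n_missing: int,
                     hospital_deliveries: list[float],
                     origin: tuple[float, float]) -> FacilityTable:
    n_first = n_disp + n_hc
    assert staffing[0] + staffing[1] + staffing[2] == n_first
    assert len(deliveries) + n_missing == n_first
    # zero-SBA facilities are dispensaries (as published); >=2 weighted to HCs
    sba = ([0] * staffing[0] + [1] * staffing[1]
           + [2 + (i % 2) for i in range(staffing[2])])
    levels = ["dispensary"] * n_disp + ["health_centre"] * n_hc
    dels: list[float | None] = list(deliveries) + [None] * n_missing
    rows = []
    x0, y0 = origin
    for i in range(n_first):
        rows.append({
            "id": f"{prefix}{i + 1:03d}", "name": f"{prefix}_fl_{i + 1:03d}",
            "level": levels[i], "x": x0 + 500.0 * (i % 12),
            "y": y0 - 500.0 * (i // 12), "sba_count": sba[i],
            "deliveries": dels[i], "offers_delivery": True,
        })
    for h, hd in enumerate(hospital_deliveries):
        rows.append({
            "id": f"{prefix}H{h + 1:02d}", "name": f"{prefix}_hospital_{h + 1}",
            "level": "hospital", "x": x0 + 250.0, "y": y0 - 250.0 * (h + 1),
            "sba_count": 10, "deliveries": hd, "offers_delivery": True,
        })
    return FacilityTable(pd.DataFrame(rows))


def iringa_reference_facilities() -> FacilityTable:
    """70 first-line facilities (64 dispensaries, 6 health centres) plus one
    hospital with 2140 deliveries; first-line deliveries total 5505 with 2
    facilities unreported."""
    return _reference_table(
        "IR", n_disp=64, n_hc=6, staffing=(2, 30, 38),
        deliveries=_IRINGA_FIRST_LINE_DELIVERIES, n_missing=2,
        hospital_deliveries=[2140.0], origin=(700000.0, 9120000.0),
    )


def ludewa_reference_facilities() -> FacilityTable:
    """52 first-line facilities (46 dispensaries, 6 health centres) plus three
    hospitals totalling 2808 deliveries; first-line deliveries total 1281 with
    7 facilities unreported."""
    return _reference_table(
        "LD", n_disp=46, n_hc=6, staffing=(12, 29, 11),
        deliveries=_LUDEWA_FIRST_LINE_DELIVERIES, n_missing=7,
        hospital_deliveries=[1500.0, 800.0, 508.0], origin=(650000.0, 8880000.0),
    )
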