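import numpy as np
import pytest
from scipy.spatial import cKDTree

import oracles
from conftest import UNIT_FRICTION, flat_pair, make_landuse, make_terrain
from ruralaccess.geodata_io import FacilityTable, RoadNetwork
from ruralaccess.network_access import (
    MeshGraph,
    generate_mesh,
    merge_roads,
    n_components,
    node_bands,
    service_area,
    shortest_times,
    weight_edges,
)
import pandas as pd


SIDE = 223.0


def small_mesh(shape=(30, 30), landuse_code=0, side=SIDE, season="dry"):
    terrain = make_terrain(np.full(shape, 1000.0), cell=90.0)
    lu = make_landuse(np.full(shape, landuse_code), cell=90.0, season=season)
    return generate_mesh(terrain.extent, side, terrain, lu), terrain, lu


class TestGenerateMesh:
    def test_edge_lengths_bounded_by_side(self):
        mesh, _, _ = small_mesh()
        assert mesh.n_edges > 0
        assert np.all(mesh.length <= SIDE + 1e-6)

    def test_edge_count_matches_geometric_pair_count(self):
        # oracle: count all node pairs at exactly one lattice spacing apart
        mesh, _, _ = small_mesh((20, 20))
        tree = cKDTree(mesh.xy)
        pairs = tree.query_pairs(SIDE * 1.001)
        true_pairs = {p for p in pairs
                      if np.hypot(*(mesh.xy[p[0]] - mesh.xy[p[1]])) > SIDE * 0.99}
        got = {tuple(sorted(e)) for e in mesh.edges}
        assert got == true_pairs

    def test_single_connected_component(self):
        mesh, _, _ = small_mesh()
        assert n_components(mesh) == 1

    def test_barrier_nodes_removed(self):
        shape = (30, 30)
        codes = np.zeros(shape)
        codes[10:20, 10:20] = 3
        terrain = make_terrain(np.full(shape, 1000.0))
        lu = make_landuse(codes)
        mesh = generate_mesh(terrain.extent, SIDE, terrain, lu)
        full, _, _ = small_mesh(shape)
        assert mesh.n_nodes < full.n_nodes
        rows = ((terrain.origin[1] - mesh.xy[:, 1]) / 90.0).astype(int)
        cols = ((mesh.xy[:, 0] - terrain.origin[0]) / 90.0).astype(int)
        assert not lu.barrier_mask[rows.clip(0, 29), cols.clip(0, 29)].any()

    def test_all_barrier_rejected(self):
        terrain = make_terrain(np.full((20, 20), 1000.0))
        lu = make_landuse(np.full((20, 20), 3))
        with pytest.raises(ValueError):
            generate_mesh(terrain.extent, SIDE, terrain, lu)

    def test_too_small_extent_rejected(self):
        terrain = make_terrain(np.full((20, 20), 1000.0))
        with pytest.raises(ValueError):
            generate_mesh((0, 0, 100.0, 100.0), SIDE, terrain)

    def test_elevations_sampled_from_dem(self):
        z = np.tile(np.arange(30) * 10.0, (30, 1))  # rises eastward
        terrain = make_terrain(z)
        mesh = generate_mesh(terrain.extent, SIDE, terrain)
        east = mesh.xy[:, 0].argmax()
        west = mesh.xy[:, 0].argmin()
        assert mesh.elevation[east] > mesh.elevation[west]


class TestWeightEdges:
    def test_level_open_dry_edge_time(self):
        # 200 m level edge, open/dry: 3 min * 0.98 (slope class) * 0.95
        xy = np.array([[0.0, 0.0], [200.0, 0.0]])
        g = MeshGraph(xy=xy, elevation=np.array([100.0, 100.0]),
                      edges=np.array([[0, 1]]), length=np.array([200.0]),
                      kind=np.array(["mesh"]),
                      road_class=np.array([""], dtype=object), side=SIDE)
        lu = make_landuse(np.zeros((5, 5)), cell=90.0)
        # place the edge inside the grid
        g.xy = g.xy + np.array([500000.0 + 10, 9000000.0 - 10])
        w = weight_edges(g, landuse=lu)
        expected = 0.2 * 15.0 * 0.98 * 0.95
        assert w.time_fwd[0] == pytest.approx(expected, abs=1e-9)
        assert w.time_rev[0] == pytest.approx(expected, abs=1e-9)

    def test_climbing_edge_asymmetric(self):
        xy = np.array([[500000.0, 9000000.0 - 10], [500200.0, 9000000.0 - 10]])
        g = MeshGraph(xy=xy, elevation=np.array([100.0, 120.0]),
                      edges=np.array([[0, 1]]), length=np.array([200.0]),
                      kind=np.array(["mesh"]),
                      road_class=np.array([""], dtype=object), side=SIDE)
        w = weight_edges(g)
        assert w.time_fwd[0] > w.time_rev[0]

    def test_tarmac_vehicle_time(self):
        xy = np.array([[500000.0, 9000000.0 - 10], [501000.0, 9000000.0 - 10]])
        g = MeshGraph(xy=xy, elevation=np.array([100.0, 100.0]),
                      edges=np.array([[0, 1]]), length=np.array([1000.0]),
                      kind=np.array(["road"]),
                      road_class=np.array(["tarmac"], dtype=object), side=SIDE)
        w = weight_edges(g)
        assert w.time_vehicle[0] == pytest.approx(0.8, abs=1e-12)

    def test_footpath_has_no_vehicle_time(self):
        xy = np.array([[500000.0, 9000000.0 - 10], [500100.0, 9000000.0 - 10]])
        g = MeshGraph(xy=xy, elevation=np.array([100.0, 100.0]),
                      edges=np.array([[0, 1]]), length=np.array([100.0]),
                      kind=np.array(["road"]),
                      road_class=np.array(["footpath"], dtype=object), side=SIDE)
        w = weight_edges(g)
        assert np.isnan(w.time_vehicle[0])

    def test_missing_elevation_rejected(self):
        xy = np.array([[0.0, 0.0], [100.0, 0.0]])
        g = MeshGraph(xy=xy, elevation=np.array([100.0, np.nan]),
                      edges=np.array([[0, 1]]), length=np.array([100.0]),
                      kind=np.array(["mesh"]),
                      road_class=np.array([""], dtype=object), side=SIDE)
        with pytest.raises(ValueError):
            weight_edges(g)


class TestMergeRoads:
    def test_empty_roads_unchanged(self):
        mesh, terrain, _ = small_mesh()
        out = merge_roads(mesh, RoadNetwork(), terrain)
        assert out is mesh

    def test_road_added_and_connected(self):
        mesh, terrain, _ = small_mesh()
        x0, y0 = terrain.origin
        road = RoadNetwork(
            [np.array([[x0 + 50, y0 - 1300], [x0 + 2500, y0 - 1300]])],
            ["tarmac"])
        out = merge_roads(mesh, road, terrain)
        assert (out.kind == "road").sum() > 0
        assert n_components(out) == 1

    def test_nearby_vertex_snapped_no_duplicate(self):
        mesh, terrain, _ = small_mesh()
        target = mesh.xy[mesh.n_nodes // 2]
        road = RoadNetwork(
            [np.array([[target[0] + 1.0, target[1]],
                       [target[0] + SIDE * 0.9, target[1]]])],
            ["motorable"])
        out = merge_roads(mesh, road, terrain, snap_tolerance=5.0)
        # the 1 m endpoint reuses the mesh node; at most one new node appears
        assert out.n_nodes <= mesh.n_nodes + 1

    def test_road_survives_barrier_lake(self):
        shape = (30, 30)
        codes = np.zeros(shape)
        codes[:, 12:17] = 3  # a lake strip
        terrain = make_terrain(np.full(shape, 1000.0))
        lu = make_landuse(codes)
        mesh = generate_mesh(terrain.extent, SIDE, terrain, lu)
        assert n_components(mesh) == 2  # lake splits the mesh
        x0, y0 = terrain.origin
        road = RoadNetwork(
            [np.array([[x0 + 100, y0 - 1350], [x0 + 2600, y0 - 1350]])],
            ["loose_surface"])
        out = merge_roads(mesh, road, terrain)
        assert n_components(out) == 1  # bridge reconnects the halves


def _random_graph(seed: int):
    """Small weighted mesh+road graph (<=200 nodes) for oracle comparison."""
    rng = np.random.default_rng(seed)
    shape = (14, 14)
    z = np.cumsum(rng.normal(0, 8, shape), axis=1) + 1000
    terrain = make_terrain(z, cell=90.0)
    lu = make_landuse(rng.choice([0, 1, 2], shape, p=[0.6, 0.3, 0.1]))
    mesh = generate_mesh(terrain.extent, 200.0, terrain, lu)
    x0, y0 = terrain.origin
    road = RoadNetwork([np.array([[x0 + 30, y0 - 700], [x0 + 1200, y0 - 700]])],
                       ["motorable"])
    mesh = merge_roads(mesh, road, terrain)
    return weight_edges(mesh, landuse=lu)


class TestShortestTimes:
    def test_single_edge_path(self):
        mesh, terrain, lu = small_mesh()
        w = weight_edges(mesh, landuse=lu)
        node = 10
        nbrs = [e for e in w.edges if node in e]
        minutes = shortest_times(w, [node])
        assert minutes[node] == 0.0
        for u, v in nbrs:
            other = v if u == node else u
            k = next(i for i, e in enumerate(w.edges)
                     if set(e) == {node, other})
            # flat open dry mesh: every edge costs length * pace * coeffs
            assert minutes[other] == pytest.approx(
                w.length[k] / 1000 * 15.0 * 0.98 * 0.95, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        g = _random_graph(seed)
        assert g.n_nodes <= 220
        rng = np.random.default_rng(seed + 99)
        sources = rng.choice(g.n_nodes, 3, replace=False).tolist()
        got = shortest_times(g, sources)
        want = oracles.graph_oracle(g.n_nodes, g.edges, g.time_fwd,
                                    g.time_rev, sources)
        assert np.allclose(got, want, atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_multimodal_dominates_pedestrian(self, seed):
        g = _random_graph(seed)
        sources = [0]
        ped = shortest_times(g, sources, mode="pedestrian")
        multi = shortest_times(g, sources, mode="multimodal")
        assert np.all(multi <= ped + 1e-9)

    def test_facility_mapping_and_distance_guard(self):
        mesh, terrain, lu = small_mesh()
        w = weight_edges(mesh, landuse=lu)
        x, y = w.xy[5]
        fac = FacilityTable(pd.DataFrame({
            "id": ["f1"], "name": ["f"], "level": ["dispensary"],
            "x": [x + 3.0], "y": [y + 3.0], "sba_count": [1],
            "deliveries": [10.0], "offers_delivery": [True],
        }))
        minutes = shortest_times(w, fac)
        assert minutes[5] == 0.0
        far = FacilityTable(pd.DataFrame({
            "id": ["f2"], "name": ["f"], "level": ["dispensary"],
            "x": [x + 1e6], "y": [y], "sba_count": [1],
            "deliveries": [10.0], "offers_delivery": [True],
        }))
        with pytest.raises(ValueError, match="mesh side"):
            shortest_times(w, far)


class TestServiceArea:
    def test_bands_nested_and_facility_at_zero(self):
        mesh, terrain, lu = small_mesh()
        w = weight_edges(mesh, landuse=lu)
        sa = service_area(w, w.n_nodes // 2, band_width=20.0, max_minutes=120.0)
        assert sa.node_minutes[w.n_nodes // 2] == 0.0
        prev: set = set()
        for k in sorted(sa.bands):
            region = prev | set(sa.band_nodes(k).tolist())
            assert set(sa.nodes_within(k * 20.0).tolist()) == region
            prev = region

    def test_isolated_component_beyond_range(self):
        shape = (30, 30)
        codes = np.zeros(shape)
        codes[:, 12:17] = 3
        terrain = make_terrain(np.full(shape, 1000.0))
        lu = make_landuse(codes)
        mesh = generate_mesh(terrain.extent, SIDE, terrain, lu)
        w = weight_edges(mesh, landuse=lu)
        west = int(np.argmin(w.xy[:, 0]))
        sa = service_area(w, west, 20.0, 120.0)
        east_nodes = w.xy[:, 0] > terrain.origin[0] + 17 * 90.0
        assert np.isinf(sa.node_minutes[east_nodes]).all()

    def test_flat_mesh_bands_are_concentric_rings(self):
        mesh, terrain, lu = small_mesh((40, 40))
        w = weight_edges(mesh, friction=UNIT_FRICTION)
        centre = int(np.argmin(np.hypot(
            w.xy[:, 0] - w.xy[:, 0].mean(), w.xy[:, 1] - w.xy[:, 1].mean())))
        sa = service_area(w, centre, 10.0, 60.0)
        d = np.hypot(*(w.xy - w.xy[centre]).T)
        pace_min_per_m = 15.0 / 1000.0
        finite = np.isfinite(sa.node_minutes) & (d > 0)
        ratio = sa.node_minutes[finite] / (d[finite] * pace_min_per_m)
        # hexagonal-lattice metric: between Euclidean and 2/sqrt(3) stretch,
        # plus one-cell discretisation slack near the centre
        slack = 200.0 / d[finite]
        assert np.all(ratio >= 1.0 - slack - 1e-9)
        assert np.all(ratio <= 2 / np.sqrt(3) + slack + 1e-9)

    def test_band_convention_matches_raster_engine(self):
        minutes = np.array([0.0, 13.5, 120.0, 120.5, np.inf])
        assert list(node_bands(minutes, 20.0, 120.0)) == [1, 1, 6, -1, -1]
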