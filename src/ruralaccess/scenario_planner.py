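"""Delivery-site reduction scenarios: greedy maximal-coverage selection with
locked hospitals, plus scenario comparison.

The published criterion — keep roughly 80% of the population within two
hours after dropping ~40% of delivery sites — is operationalised as greedy
maximal coverage: starting from the locked set, repeatedly add the facility
that brings the most additional population inside the 120-minute threshold,
breaking ties by facility id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage_stats import CoverageTable, _cumulative
from .geodata_io import FacilityTable, PopulationGrid

__all__ = [
    "Scenario",
    "PrecomputedAccess",
    "precompute_raster_access",
    "precompute_network_access",
    "reduce_sites",
    "compare",
]


@dataclass
class PrecomputedAccess:
    """Per-facility travel times to every demand unit.

    ``times``: (n_facilities, n_units) minutes; ``weights``: persons per unit.
    Rows are ordered like ``facility_ids``.
    """

    facility_ids: tuple
    times: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.times.shape != (len(self.facility_ids), len(self.weights)):
            raise ValueError("times must be (n_facilities, n_units)")

    def min_times(self, ids) -> np.ndarray:
        sel = [self.facility_ids.index(i) for i in ids]
        if not sel:
            return np.full(self.times.shape[1], np.inf)
        return self.times[sel].min(axis=0)

    def coverage_table(self, ids, band_width=20.0, max_minutes=120.0,
                       thresholds=(60.0, 120.0), scenario_id="scenario",
                       ) -> CoverageTable:
        return _cumulative(self.min_times(ids), self.weights, scenario_id,
                           band_width, max_minutes, thresholds)

    def covered_population(self, ids, threshold: float = 120.0) -> float:
        t = self.min_times(ids)
        return float(self.weights[np.isfinite(t) & (t <= threshold + 1e-12)].sum())


def precompute_raster_access(ctx, facilities: FacilityTable,
                             pop: PopulationGrid) -> PrecomputedAccess:
    """One travel-time surface per facility on the raster engine."""
    from scipy.sparse.csgraph import dijkstra

    from .raster_access import _move_graph, _source_cells

    graph = _move_graph(ctx).T
    ids, flats = [], []
    for _, row in facilities.frame.iterrows():
        flat, _ = _source_cells(ctx, facilities.subset([row["id"]]))
        ids.append(row["id"])
        flats.append(flat[0])
    dist = dijkstra(graph, directed=True, indices=flats)
    weights = pop.data.ravel()
    return PrecomputedAccess(tuple(ids), dist, weights)


def precompute_network_access(graph, facilities: FacilityTable,
                              pop: PopulationGrid, mode: str = "pedestrian",
                              ) -> PrecomputedAccess:
    """One per-node time vector per facility, demand at populated cells."""
    from .coverage_stats import allocate_population_to_nodes
    from .network_access import facility_nodes, shortest_times

    node_of = facility_nodes(graph, facilities)
    alloc, persons = allocate_population_to_nodes(graph, pop)
    rows = []
    for fid, node in node_of.items():
        minutes = shortest_times(graph, [node], mode=mode)
        rows.append(minutes[alloc])
    return PrecomputedAccess(tuple(node_of), np.array(rows), persons)


@dataclass
class Scenario:
    """A selected facility set with its coverage table."""

    scenario_id: str
    selected_ids: tuple
    locked_ids: tuple
    coverage: CoverageTable
    selection_order: tuple = ()
    deltas_vs_baseline: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.locked_ids) <= set(self.selected_ids):
            raise ValueError("locked facilities must be selected")

    def to_frame(self, all_ids=None) -> pd.DataFrame:
        ids = list(all_ids) if all_ids is not None else list(self.selected_ids)
        return pd.DataFrame({
            "id": ids,
            "selected": [i in set(self.selected_ids) for i in ids],
            "locked": [i in set(self.locked_ids) for i in ids],
        })


def reduce_sites(facilities: FacilityTable, access: PrecomputedAccess,
                 target_count: int | None = None,
                 min_coverage_pct: float | None = None,
                 threshold: float = 120.0,
                 band_width: float = 20.0, max_minutes: float = 120.0,
                 thresholds=(60.0, 120.0),
                 scenario_id: str = "reduced") -> Scenario:
    """Greedy maximal-coverage facility selection.

    Hospitals are locked in; facilities are added by largest gain in
    population within ``threshold`` minutes until ``target_count`` facilities
    are selected or ``min_coverage_pct`` is reached.  Deterministic; ties go
    to the smaller facility id.
    """
    if (target_count is None) == (min_coverage_pct is None):
        raise ValueError("give exactly one of target_count/min_coverage_pct")
    df = facilities.frame
    all_ids = [i for i in access.facility_ids if i in set(df["id"])]
    locked = sorted(df.loc[df["level"] == "hospital", "id"])
    locked = [i for i in locked if i in all_ids]
    total = float(access.weights.sum())
    baseline_cov = access.covered_population(all_ids, threshold) / total * 100

    if min_coverage_pct is not None and min_coverage_pct > baseline_cov + 1e-9:
        raise ValueError(
            f"coverage target {min_coverage_pct}% exceeds the baseline "
            f"{baseline_cov:.1f}% achievable with all facilities")
    if target_count is not None:
        if target_count < len(locked):
            raise ValueError("target count smaller than the locked set")
        target_count = min(target_count, len(all_ids))

    selected = list(locked)
    order = list(locked)
    current = access.min_times(selected) if selected else np.full(
        access.times.shape[1], np.inf)
    idx_of = {fid: k for k, fid in enumerate(access.facility_ids)}

    def covered_pct(times):
        w = access.weights[np.isfinite(times) & (times <= threshold + 1e-12)]
        return float(w.sum()) / total * 100

    remaining = sorted(set(all_ids) - set(selected))
    while remaining:
        if target_count is not None and len(selected) >= target_count:
            break
        if min_coverage_pct is not None and covered_pct(current) >= min_coverage_pct - 1e-9:
            break
        best_id, best_gain = None, -1.0
        uncovered = ~(np.isfinite(current) & (current <= threshold + 1e-12))
        for fid in remaining:  # sorted -> deterministic tie-break by id
            t = access.times[idx_of[fid]]
            gain = float(access.weights[
                uncovered & np.isfinite(t) & (t <= threshold + 1e-12)].sum())
            if gain > best_gain + 1e-12:
                best_id, best_gain = fid, gain
        selected.append(best_id)
        order.append(best_id)
        remaining.remove(best_id)
        current = np.minimum(current, access.times[idx_of[best_id]])

    cov = access.coverage_table(selected, band_width, max_minutes, thresholds,
                                scenario_id)
    return Scenario(scenario_id, tuple(sorted(selected, key=str)),
                    tuple(locked), cov, selection_order=tuple(order))


def compare(baseline: Scenario, reduced: Scenario) -> pd.DataFrame:
    """Per-threshold percentage-point differences (reduced minus baseline)."""
    b, r = baseline.coverage, reduced.coverage
    if (b.band_width != r.band_width
            or set(b.thresholds_pct) != set(r.thresholds_pct)):
        raise ValueError("scenarios use different band definitions")
    rows = []
    for thr in sorted(b.thresholds_pct):
        rows.append({
            "threshold_min": thr,
            "baseline_pct": round(b.thresholds_pct[thr], 1),
            "reduced_pct": round(r.thresholds_pct[thr], 1),
            "delta_pp": round(r.thresholds_pct[thr] - b.thresholds_pct[thr], 1),
        })
    return pd.DataFrame(rows)


def lost_access_mask(access: PrecomputedAccess, baseline_ids, reduced_ids,
                     threshold: float = 120.0) -> np.ndarray:
    """Demand units within the threshold at baseline but not after reduction."""
    tb = access.min_times(list(baseline_ids))
    tr = access.min_times(list(reduced_ids))
    inb = np.isfinite(tb) & (tb <= threshold + 1e-12)
    inr = np.isfinite(tr) & (tr <= threshold + 1e-12)
    return inb & ~inr
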