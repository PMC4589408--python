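"""Population coverage by travel-time bands and facility descriptive
statistics (staffing classes, caseload classes, medians, hospital share)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geodata_io import FacilityTable, PopulationGrid
from .network_access import MeshGraph
from .raster_access import TravelTimeSurface

__all__ = [
    "CoverageTable",
    "FacilitySummary",
    "coverage",
    "coverage_from_nodes",
    "facility_summary",
    "hospital_share",
    "STAFFING_CLASSES",
    "CASELOAD_CLASSES",
]

STAFFING_CLASSES = ("0", "1", ">=2")
CASELOAD_CLASSES = ("0-49", "50-99", "100-199", ">=200", "missing")


@dataclass
class CoverageTable:
    """Cumulative % of population by travel-time band plus threshold rows."""

    scenario_id: str
    band_width: float
    max_minutes: float
    cumulative_pct: dict  # band upper bound (minutes) -> cumulative %
    thresholds_pct: dict  # threshold minutes -> cumulative %
    total_population: float

    def pct_within(self, minutes: float) -> float:
        if minutes in self.thresholds_pct:
            return self.thresholds_pct[minutes]
        if minutes in self.cumulative_pct:
            return self.cumulative_pct[minutes]
        raise KeyError(f"no band or threshold at {minutes} minutes")

    @property
    def beyond_pct(self) -> float:
        return 100.0 - self.thresholds_pct[max(self.thresholds_pct)]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"bound_min": b, "cumulative_pct": round(p, 1)}
                for b, p in sorted(self.cumulative_pct.items())]
        for thr, p in sorted(self.thresholds_pct.items()):
            rows.append({"bound_min": thr, "cumulative_pct": round(p, 1)})
        df = pd.DataFrame(rows).drop_duplicates("bound_min").sort_values("bound_min")
        df["scenario"] = self.scenario_id
        return df.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _cumulative(times: np.ndarray, weights: np.ndarray, scenario_id: str,
                band_width: float, max_minutes: float,
                thresholds: tuple[float, ...]) -> CoverageTable:
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("zero total population")
    finite = np.isfinite(times)
    bands = np.arange(band_width, max_minutes + band_width / 2, band_width)
    cum = {}
    for b in bands:
        inside = finite & (times <= b + 1e-12)
        cum[float(b)] = float(weights[inside].sum()) / total * 100.0
    thr = {}
    for t in thresholds:
        inside = finite & (times <= t + 1e-12)
        thr[float(t)] = float(weights[inside].sum()) / total * 100.0
    return CoverageTable(scenario_id, band_width, max_minutes, cum, thr, total)


def coverage(surface: TravelTimeSurface, pop: PopulationGrid,
             band_width: float = 20.0, max_minutes: float = 120.0,
             thresholds: tuple[float, ...] = (60.0, 120.0),
             scenario_id: str = "baseline") -> CoverageTable:
    """Zonal statistics of population over a raster travel-time surface."""
    if pop.shape != surface.minutes.shape:
        raise ValueError("population grid must be aligned to the surface")
    return _cumulative(surface.minutes.ravel(), pop.data.ravel(), scenario_id,
                       band_width, max_minutes, thresholds)


def allocate_population_to_nodes(graph: MeshGraph, pop: PopulationGrid,
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Assign each populated cell to its nearest graph node.

    Returns (node index per populated cell, persons per populated cell).
    """
    rows, cols = np.nonzero(pop.data > 0)
    if len(rows) == 0:
        raise ValueError("zero total population")
    cs = pop.cell_size
    x0, y0 = pop.origin
    xy = np.column_stack([x0 + (cols + 0.5) * cs, y0 - (rows + 0.5) * cs])
    tree = cKDTree(graph.xy)
    _, node = tree.query(xy)
    return node.astype(int), pop.data[rows, cols]


def coverage_from_nodes(node_minutes: np.ndarray, graph: MeshGraph,
                        pop: PopulationGrid, band_width: float = 20.0,
                        max_minutes: float = 120.0,
                        thresholds: tuple[float, ...] = (60.0, 120.0),
                        scenario_id: str = "baseline") -> CoverageTable:
    """Coverage table from per-node travel times (network engine)."""
    node, persons = allocate_population_to_nodes(graph, pop)
    return _cumulative(node_minutes[node], persons, scenario_id, band_width,
                       max_minutes, thresholds)


@dataclass
class FacilitySummary:
    """First-line staffing/caseload class counts plus hospital share."""

    n_first_line: int
    staffing_counts: dict = field(default_factory=dict)
    caseload_counts: dict = field(default_factory=dict)
    median_caseload: float = float("nan")
    caseload_range: tuple = (float("nan"), float("nan"))
    n_reported_first_line: int = 0
    hospital_share_pct: float = float("nan")

    def staffing_pct(self, cls: str, decimals: int = 1) -> float:
        return round(self.staffing_counts[cls] / self.n_first_line * 100, decimals)

    def understaffed_pct(self, decimals: int = 1) -> float:
        """% of first-line facilities with fewer than two skilled attendants."""
        n = self.staffing_counts["0"] + self.staffing_counts["1"]
        return round(n / self.n_first_line * 100, decimals)

    def low_caseload_count(self) -> int:
        """First-line facilities with a reported caseload below 100."""
        return self.caseload_counts["0-49"] + self.caseload_counts["50-99"]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"table": "staffing", "class": k, "n": v}
                for k, v in self.staffing_counts.items()]
        rows += [{"table": "caseload", "class": k, "n": v}
                 for k, v in self.caseload_counts.items()]
        return pd.DataFrame(rows)


def facility_summary(table: FacilityTable) -> FacilitySummary:
    """Descriptive statistics over first-line facilities (hospitals excluded
    from the classes; missing caseloads counted separately and excluded from
    the median/range)."""
    if len(table) == 0:
        raise ValueError("facility table is empty")
    fl = table.first_line
    sba = fl["sba_count"]
    staffing = {
        "0": int((sba == 0).sum()),
        "1": int((sba == 1).sum()),
        ">=2": int((sba >= 2).sum()),
    }
    dels = fl["deliveries"]
    reported = dels.dropna()
    caseload = {
        "0-49": int((reported < 50).sum()),
        "50-99": int(((reported >= 50) & (reported < 100)).sum()),
        "100-199": int(((reported >= 100) & (reported < 200)).sum()),
        ">=200": int((reported >= 200).sum()),
        "missing": int(dels.isna().sum()),
    }
    median = float(reported.median()) if len(reported) else float("nan")
    rng = ((float(reported.min()), float(reported.max())) if len(reported)
           else (float("nan"), float("nan")))
    try:
        share = hospital_share(table)
    except ValueError:
        share = float("nan")
    return FacilitySummary(
        n_first_line=len(fl),
        staffing_counts=staffing,
        caseload_counts=caseload,
        median_caseload=median,
        caseload_range=rng,
        n_reported_first_line=int(len(reported)),
        hospital_share_pct=share,
    )


def hospital_share(table: FacilityTable, decimals: int | None = None) -> float:
    """Hospital deliveries as a percentage of all reported deliveries."""
    hosp = table.hospitals["deliveries"].dropna()
    if len(hosp) == 0:
        raise ValueError("no hospital with reported deliveries")
    total = table.frame["deliveries"].dropna().sum()
    if total <= 0:
        raise ValueError("no reported deliveries")
    pct = float(hosp.sum()) / float(total) * 100.0
    return round(pct, decimals) if decimals is not None else pct
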