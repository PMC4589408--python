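"""Raster/vector/tabular I/O, grid alignment, and run configuration.

Rasters are single-band GeoTIFFs (read and written through ``tifffile`` with
the georeferencing tags handled here) or ESRI ASCII grids; vectors are
GeoJSON; facility and coverage tables are CSV.  All computation happens in a
projected metric CRS — rasters georeferenced in degrees are rejected with a
pointer to the :func:`utm_from_wgs84` helper rather than silently reprojected.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .speed_model import LANDUSE_CLASSES, ROAD_CLASSES, SEASONS

__all__ = [
    "Grid",
    "TerrainModel",
    "LandUseGrid",
    "PopulationGrid",
    "RoadNetwork",
    "FacilityTable",
    "RunConfig",
    "read_raster",
    "write_raster",
    "rescale_population",
    "align_grids",
    "read_roads_geojson",
    "write_roads_geojson",
    "read_facilities_csv",
    "write_facilities_csv",
    "write_facilities_geojson",
    "read_config",
    "write_config",
    "utm_from_wgs84",
    "wgs84_from_utm",
    "LANDUSE_CODES",
    "LANDUSE_NAMES",
    "FACILITY_LEVELS",
]

# integer raster codes for land-use categories
LANDUSE_CODES = {"open": 0, "bushy": 1, "forest": 2, "barrier": 3}
LANDUSE_NAMES = {v: k for k, v in LANDUSE_CODES.items()}

FACILITY_LEVELS = ("dispensary", "health_centre", "hospital")

# GeoTIFF tag ids
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

_GEOKEY_MODEL_TYPE = 1024
_GEOKEY_RASTER_TYPE = 1025
_GEOKEY_GEOGRAPHIC_CS = 2048
_GEOKEY_PROJECTED_CS = 3072
_MODEL_PROJECTED = 1
_MODEL_GEOGRAPHIC = 2


def _parse_epsg(crs_id) -> int:
    if isinstance(crs_id, int):
        return crs_id
    m = re.fullmatch(r"(?i)epsg:\s*(\d+)", str(crs_id).strip())
    if not m:
        raise ValueError(f"cannot parse CRS identifier {crs_id!r}; use 'EPSG:<code>'")
    return int(m.group(1))


def crs_is_geographic(crs_id) -> bool:
    """True when the EPSG code denotes a geodetic (degree-based) CRS.

    EPSG reserves the 4000-4999 block for geodetic CRSs; that heuristic covers
    WGS84 (4326) and the datums relevant here.
    """
    code = _parse_epsg(crs_id)
    return 4000 <= code <= 4999


class GeographicCRSError(ValueError):
    pass


@dataclass
class Grid:
    """A single-band georeferenced raster in a projected metric CRS.

    ``origin`` is the (x, y) of the *outer corner* of the top-left cell; rows
    run north to south, so the cell centre of (row, col) is
    ``(x0 + (col + .5) * cell, y0 - (row + .5) * cell)``.
    """

    data: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    crs_id: str = "EPSG:32736"
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("grid data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if crs_is_geographic(self.crs_id):
            raise GeographicCRSError(
                f"{self.crs_id} is a geographic (degree) CRS; reproject to a "
                "metric CRS first (see utm_from_wgs84)"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.data.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.data.shape:
                raise ValueError("nodata mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-9)
            and math.isclose(self.origin[0], other.origin[0], abs_tol=1e-6)
            and math.isclose(self.origin[1], other.origin[1], abs_tol=1e-6)
            and _parse_epsg(self.crs_id) == _parse_epsg(other.crs_id)
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin
        col = int(math.floor((x - x0) / self.cell_size))
        row = int(math.floor((y0 - y) / self.cell_size))
        if not (0 <= row < self.shape[0] and 0 <= col < self.shape[1]):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        x0, y0 = self.origin
        ny, nx = self.shape
        return (x0, y0 - ny * self.cell_size, x0 + nx * self.cell_size, y0)


class TerrainModel(Grid):
    """Elevation grid (metres above sea level)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(float)
        valid = ~self.nodata_mask
        if valid.any() and not np.all(np.isfinite(self.data[valid])):
            raise ValueError("non-masked elevations must be finite")


class LandUseGrid(Grid):
    """Per-cell land-use category codes (see LANDUSE_CODES) plus a season."""

    def __init__(self, data, cell_size, origin, crs_id="EPSG:32736",
                 nodata_mask=None, season: str = "dry"):
        if season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}")
        self.season = season
        super().__init__(data, cell_size, origin, crs_id, nodata_mask)
        self.data = self.data.astype(np.uint8)
        if self.data.max(initial=0) > max(LANDUSE_CODES.values()):
            raise ValueError("unknown land-use code in grid")

    @property
    def barrier_mask(self) -> np.ndarray:
        return self.data == LANDUSE_CODES["barrier"]


class PopulationGrid(Grid):
    """Persons per cell."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(float)
        self.data[self.nodata_mask] = 0.0
        if np.any(self.data < 0):
            raise ValueError("population must be non-negative")

    @property
    def total_population(self) -> float:
        return float(self.data.sum())


_KINDS = {"terrain": TerrainModel, "landuse": LandUseGrid, "population": PopulationGrid,
          "grid": Grid}


def _geokeys_epsg(keys: np.ndarray) -> tuple[int | None, bool]:
    """Return (epsg, is_geographic) from a GeoKeyDirectory short array."""
    keys = np.asarray(keys).ravel()
    epsg = None
    model = None
    n = int(keys[3])
    for i in range(1, n + 1):
        kid, loc, cnt, val = keys[4 * i: 4 * i + 4]
        if kid == _GEOKEY_MODEL_TYPE:
            model = int(val)
        elif kid == _GEOKEY_PROJECTED_CS:
            epsg = int(val)
        elif kid == _GEOKEY_GEOGRAPHIC_CS and epsg is None:
            epsg = int(val)
    return epsg, model == _MODEL_GEOGRAPHIC


def read_raster(path, kind: str = "grid", **kwargs) -> Grid:
    """Read a single-band GeoTIFF or ESRI ASCII grid.

    ``kind`` selects the returned type: terrain | landuse | population | grid.
    Extra keyword arguments (e.g. ``season``) go to the grid constructor.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".asc", ".agr"):
        return _read_ascii_grid(path, kind, **kwargs)

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim == 3 and data.shape[0] == 1:
            data = data[0]
        if data.ndim != 2:
            raise ValueError("expected a single-band raster")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path} has no georeference (pixel scale/tiepoint)")
        sx, sy, _ = tags[_TAG_PIXEL_SCALE].value[:3]
        tie = tags[_TAG_TIEPOINT].value
        origin = (float(tie[3]) - float(tie[0]) * sx, float(tie[4]) + float(tie[1]) * sy)
        crs_id, geographic = None, False
        if _TAG_GEOKEYS in tags:
            crs_id, geographic = _geokeys_epsg(tags[_TAG_GEOKEYS].value)
        if geographic or (crs_id is not None and crs_is_geographic(crs_id)):
            raise GeographicCRSError(
                f"{path} is georeferenced in degrees; reproject to a metric "
                "CRS (e.g. a UTM zone) before use"
            )
        if not math.isclose(sx, sy, rel_tol=1e-6):
            raise ValueError("only square cells are supported")
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00"))
        mask = None
        if nodata is not None:
            mask = (np.isnan(data) if math.isnan(nodata) else data == nodata)
    cls = _KINDS[kind]
    crs = f"EPSG:{crs_id}" if crs_id else "EPSG:32736"
    return cls(data, float(sx), origin, crs, mask, **kwargs)


def write_raster(path, grid: Grid, nodata: float | None = None) -> None:
    """Write a grid as a georeferenced single-band GeoTIFF or ASCII grid."""
    path = Path(path)
    if path.suffix.lower() in (".asc", ".agr"):
        _write_ascii_grid(path, grid, nodata)
        return
    data = np.array(grid.data)
    if nodata is None:
        nodata = -9999.0 if np.issubdtype(data.dtype, np.floating) else 255
    if grid.nodata_mask.any():
        data = data.copy()
        data[grid.nodata_mask] = nodata
    epsg = _parse_epsg(grid.crs_id)
    geokeys = np.array(
        [1, 1, 0, 3,
         _GEOKEY_MODEL_TYPE, 0, 1, _MODEL_PROJECTED,
         _GEOKEY_RASTER_TYPE, 0, 1, 1,
         _GEOKEY_PROJECTED_CS, 0, 1, epsg],
        dtype=np.uint16,
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), tuple(int(v) for v in geokeys)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def _read_ascii_grid(path: Path, kind: str, **kwargs) -> Grid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value", "epsg",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    data = np.array(rows)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + data.shape[0] * cell)
    nodata = header.get("nodata_value")
    mask = (data == nodata) if nodata is not None else None
    crs = f"EPSG:{int(header['epsg'])}" if "epsg" in header else "EPSG:32736"
    return _KINDS[kind](data, cell, origin, crs, mask, **kwargs)


def _write_ascii_grid(path: Path, grid: Grid, nodata: float | None) -> None:
    nodata = -9999.0 if nodata is None else nodata
    data = np.array(grid.data, dtype=float)
    data[grid.nodata_mask] = nodata
    ny, nx = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1] - ny * grid.cell_size:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"nodata_value {nodata}\n")
        fh.write(f"epsg {_parse_epsg(grid.crs_id)}\n")
        for row in data:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# population handling

def rescale_population(pop: PopulationGrid, census_total: float) -> PopulationGrid:
    """Scale every cell by one factor so the grid total matches the census,
    leaving the spatial distribution untouched."""
    if census_total <= 0:
        raise ValueError("census total must be positive")
    current = pop.total_population
    if current <= 0:
        raise ValueError("population grid is empty")
    factor = census_total / current
    return PopulationGrid(pop.data * factor, pop.cell_size, pop.origin,
                          pop.crs_id, pop.nodata_mask.copy())


def _overlap_matrix(src_start, src_cell, n_src, dst_start, dst_cell, n_dst,
                    descending=False):
    """Fractional overlap of source intervals with target intervals along one
    axis; each row of the result sums to 1 where covered (mass split by area)."""
    sgn = -1.0 if descending else 1.0
    src_edges = src_start + sgn * src_cell * np.arange(n_src + 1)
    dst_edges = dst_start + sgn * dst_cell * np.arange(n_dst + 1)
    if descending:
        src_edges, dst_edges = -src_edges, -dst_edges
    lo = np.maximum(src_edges[:-1, None], dst_edges[None, :-1])
    hi = np.minimum(src_edges[1:, None], dst_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None) / src_cell


def resample_population(pop: PopulationGrid, target: Grid) -> PopulationGrid:
    """Area-weighted, mass-conserving regrid of population onto the target
    geometry.  Mass in parts of the source footprint not covered by the target
    is dropped (and vice versa no mass is invented)."""
    wx = _overlap_matrix(pop.origin[0], pop.cell_size, pop.shape[1],
                         target.origin[0], target.cell_size, target.shape[1])
    wy = _overlap_matrix(pop.origin[1], pop.cell_size, pop.shape[0],
                         target.origin[1], target.cell_size, target.shape[0],
                         descending=True)
    data = wy.T @ pop.data @ wx
    return PopulationGrid(data, target.cell_size, target.origin, target.crs_id)


def align_grids(primary: Grid, **others: Grid) -> dict[str, Grid]:
    """Bring named grids onto the primary grid's geometry.

    Grids that already share the geometry pass through unchanged; population
    grids are resampled conservatively; anything else must match exactly.
    """
    out: dict[str, Grid] = {}
    for name, grid in others.items():
        if _parse_epsg(grid.crs_id) != _parse_epsg(primary.crs_id):
            raise ValueError(f"{name}: CRS mismatch with primary grid")
        e1, e2 = primary.extent, grid.extent
        if e1[2] <= e2[0] or e2[2] <= e1[0] or e1[3] <= e2[1] or e2[3] <= e1[1]:
            raise ValueError(f"{name}: extent disjoint from primary grid")
        if grid.same_geometry(primary):
            out[name] = grid
        elif isinstance(grid, PopulationGrid):
            out[name] = resample_population(grid, primary)
        else:
            raise ValueError(
                f"{name}: grid geometry differs from primary; only population "
                "grids are resampled automatically"
            )
    return out


# ---------------------------------------------------------------------------
# vector + tabular I/O

@dataclass
class RoadNetwork:
    """Classified road polylines in projected coordinates."""

    segments: list[np.ndarray] = field(default_factory=list)
    road_classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.road_classes):
            raise ValueError("one class per segment required")
        self.segments = [np.asarray(s, dtype=float) for s in self.segments]
        for seg in self.segments:
            if seg.ndim != 2 or seg.shape[0] < 2 or seg.shape[1] != 2:
                raise ValueError("segments must be (N>=2, 2) vertex arrays")
        for cls in self.road_classes:
            if cls not in ROAD_CLASSES:
                raise ValueError(f"unknown road class {cls!r}")

    def __len__(self) -> int:
        return len(self.segments)

    def total_length(self) -> float:
        return float(sum(np.hypot(*np.diff(s, axis=0).T).sum() for s in self.segments))


def read_roads_geojson(path) -> RoadNetwork:
    with open(path) as fh:
        gj = json.load(fh)
    segments, classes = [], []
    for feat in gj.get("features", []):
        geom = feat.get("geometry") or {}
        cls = (feat.get("properties") or {}).get("road_class", "footpath")
        if geom.get("type") == "LineString":
            parts = [geom["coordinates"]]
        elif geom.get("type") == "MultiLineString":
            parts = geom["coordinates"]
        else:
            continue
        for coords in parts:
            segments.append(np.asarray(coords, dtype=float)[:, :2])
            classes.append(cls)
    return RoadNetwork(segments, classes)


def write_roads_geojson(path, roads: RoadNetwork, crs_id: str = "EPSG:32736") -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"road_class": cls},
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)] for x, y in seg]},
        }
        for seg, cls in zip(roads.segments, roads.road_classes)
    ]
    gj = {"type": "FeatureCollection", "crs_id": crs_id, "features": feats}
    with open(path, "w") as fh:
        json.dump(gj, fh)


_FACILITY_COLUMNS = ["id", "name", "level", "x", "y", "sba_count", "deliveries",
                     "offers_delivery"]


@dataclass
class FacilityTable:
    """Facility records; ``deliveries`` may be missing (NaN)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in _FACILITY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"facility table missing columns: {missing}")
        if df["id"].duplicated().any():
            raise ValueError("facility ids must be unique")
        bad = ~df["level"].isin(FACILITY_LEVELS)
        if bad.any():
            raise ValueError(f"unknown facility level(s): {sorted(df.loc[bad, 'level'])}")
        df["sba_count"] = df["sba_count"].astype(int)
        if (df["sba_count"] < 0).any():
            raise ValueError("sba_count must be non-negative")
        df["deliveries"] = pd.to_numeric(df["deliveries"], errors="coerce")
        if (df["deliveries"].dropna() < 0).any():
            raise ValueError("deliveries must be non-negative")
        df["offers_delivery"] = df["offers_delivery"].astype(bool)
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def first_line(self) -> pd.DataFrame:
        return self.frame[self.frame["level"] != "hospital"]

    @property
    def hospitals(self) -> pd.DataFrame:
        return self.frame[self.frame["level"] == "hospital"]

    def delivery_sites(self) -> "FacilityTable":
        return FacilityTable(self.frame[self.frame["offers_delivery"]].copy())

    def subset(self, ids) -> "FacilityTable":
        ids = set(ids)
        return FacilityTable(self.frame[self.frame["id"].isin(ids)].copy())

    def check_extent(self, extent: tuple[float, float, float, float]) -> None:
        xmin, ymin, xmax, ymax = extent
        ok = (self.frame["x"].between(xmin, xmax)
              & self.frame["y"].between(ymin, ymax))
        if not ok.all():
            bad = list(self.frame.loc[~ok, "id"])
            raise ValueError(f"facilities outside study extent: {bad}")


def read_facilities_csv(path) -> FacilityTable:
    df = pd.read_csv(path, dtype={"id": str, "name": str, "level": str})
    return FacilityTable(df)


def write_facilities_csv(path, table: FacilityTable) -> None:
    df = table.frame.copy()
    # missing deliveries as empty field, others as plain integers
    df["deliveries"] = df["deliveries"].map(
        lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False, columns=_FACILITY_COLUMNS,
              quoting=csv.QUOTE_MINIMAL)


def write_facilities_geojson(path, table: FacilityTable,
                             crs_id: str = "EPSG:32736") -> None:
    feats = []
    for _, row in table.frame.iterrows():
        props = {k: row[k] for k in ("id", "name", "level", "sba_count",
                                     "offers_delivery")}
        props["deliveries"] = None if pd.isna(row["deliveries"]) else float(row["deliveries"])
        feats.append({
            "type": "Feature",
            "properties": props,
            "geometry": {"type": "Point",
                         "coordinates": [float(row["x"]), float(row["y"])]},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "crs_id": crs_id,
                   "features": feats}, fh)


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class RunConfig:
    season: str = "dry"
    mode: str = "pedestrian"
    band_width_min: float = 20.0
    thresholds_min: tuple[float, ...] = (60.0, 120.0)
    mesh_side_m: float = 223.0
    connectivity: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}")
        if self.mode not in ("pedestrian", "multimodal"):
            raise ValueError("mode must be pedestrian or multimodal")
        if self.band_width_min <= 0:
            raise ValueError("band width must be positive")
        if list(self.thresholds_min) != sorted(set(self.thresholds_min)):
            raise ValueError("thresholds must be strictly increasing")
        if self.connectivity not in (8, 16):
            raise ValueError("connectivity must be 8 or 16")
        maxthr = max(self.thresholds_min)
        if abs(maxthr / self.band_width_min - round(maxthr / self.band_width_min)) > 1e-9:
            raise ValueError("band width must divide the maximum threshold")

    @property
    def max_minutes(self) -> float:
        return max(self.thresholds_min)


def read_config(path) -> RunConfig:
    """Parse a `key = value` text file into a RunConfig (unknown keys rejected)."""
    kwargs: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key = value")
            key, val = (p.strip() for p in line.split("=", 1))
            if key == "season" or key == "mode":
                kwargs[key] = val
            elif key == "band_width_min" or key == "mesh_side_m":
                kwargs[key] = float(val)
            elif key == "thresholds_min":
                kwargs[key] = tuple(float(v) for v in val.split(","))
            elif key in ("connectivity", "seed"):
                kwargs[key] = int(val)
            else:
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
    return RunConfig(**kwargs)


def write_config(path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"season = {cfg.season}\n")
        fh.write(f"mode = {cfg.mode}\n")
        fh.write(f"band_width_min = {cfg.band_width_min}\n")
        fh.write("thresholds_min = " + ",".join(str(t) for t in cfg.thresholds_min) + "\n")
        fh.write(f"mesh_side_m = {cfg.mesh_side_m}\n")
        fh.write(f"connectivity = {cfg.connectivity}\n")
        fh.write(f"seed = {cfg.seed}\n")


# ---------------------------------------------------------------------------
# minimal WGS84 <-> UTM transverse-Mercator helper (no external CRS engine)

_WGS84_A = 6378137.0
_WGS84_F = 1 / 298.257223563
_UTM_K0 = 0.9996


def _tm_constants():
    f = _WGS84_F
    n = f / (2 - f)
    a1 = _WGS84_A / (1 + n) * (1 + n * n / 4 + n ** 4 / 64)
    alpha = (
        n / 2 - 2 * n ** 2 / 3 + 5 * n ** 3 / 16,
        13 * n ** 2 / 48 - 3 * n ** 3 / 5,
        61 * n ** 3 / 240,
    )
    beta = (
        n / 2 - 2 * n ** 2 / 3 + 37 * n ** 3 / 96,
        n ** 2 / 48 + n ** 3 / 15,
        17 * n ** 3 / 480,
    )
    return n, a1, alpha, beta


def utm_from_wgs84(lon_deg: float, lat_deg: float, zone: int,
                   south: bool = True) -> tuple[float, float]:
    """Forward transverse-Mercator projection of a WGS84 lon/lat into a UTM
    zone (Karney-Krüger series, millimetre-level for in-zone points)."""
    n, a1, alpha, _ = _tm_constants()
    lat = math.radians(lat_deg)
    lon0 = math.radians(zone * 6 - 183)
    dlon = math.radians(lon_deg) - lon0
    e = math.sqrt(_WGS84_F * (2 - _WGS84_F))
    t = math.sinh(math.atanh(math.sin(lat)) - e * math.atanh(e * math.sin(lat)))
    xi = math.atan2(t, math.cos(dlon))
    eta = math.asinh(math.sin(dlon) / math.hypot(t, math.cos(dlon)))
    x, y = eta, xi
    for j, a in enumerate(alpha, start=1):
        x += a * math.cos(2 * j * xi) * math.sinh(2 * j * eta)
        y += a * math.sin(2 * j * xi) * math.cosh(2 * j * eta)
    easting = 500000.0 + _UTM_K0 * a1 * x
    northing = _UTM_K0 * a1 * y + (10000000.0 if south else 0.0)
    return easting, northing


def wgs84_from_utm(easting: float, northing: float, zone: int,
                   south: bool = True) -> tuple[float, float]:
    """Inverse of :func:`utm_from_wgs84`."""
    n, a1, _, beta = _tm_constants()
    x = (easting - 500000.0) / (_UTM_K0 * a1)
    y = (northing - (10000000.0 if south else 0.0)) / (_UTM_K0 * a1)
    xi, eta = y, x
    for j, b in enumerate(beta, start=1):
        xi -= b * math.sin(2 * j * y) * math.cosh(2 * j * x)
        eta -= b * math.cos(2 * j * y) * math.sinh(2 * j * x)
    chi = math.asin(math.sin(xi) / math.cosh(eta))
    e = math.sqrt(_WGS84_F * (2 - _WGS84_F))
    lat = chi
    for _ in range(8):  # conformal -> geodetic latitude, fixed point
        lat = math.asin(math.tanh(
            math.atanh(math.sin(chi)) + e * math.atanh(e * math.sin(lat))))
    lon0 = zone * 6 - 183
    lon = lon0 + math.degrees(math.atan2(math.sinh(eta), math.cos(xi)))
    return lon, math.degrees(lat)
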