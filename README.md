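# ruralaccess

Travel-time accessibility modelling for rural health services. Two
independent engines estimate how long it takes to walk (or walk + ride) from
anywhere in a district to the nearest health facility over rugged terrain:

* **raster engine** — an anisotropic cost surface over a 90 m elevation grid.
  The slope along each move drives a slope-adjusted walking-pace rule
  (4 km/h basal; +0.1 min per metre climbed; −0.03 min per metre descended
  between 5° and 12°, +0.03 min per metre on steeper descents); slope-class
  and land-use/season friction coefficients multiply crossing times; lakes
  and swamps are impassable. Travel times are accumulated with exact
  multi-source shortest paths over an 8- or 16-connected move graph.
* **network engine** — a virtual triangular mesh (edge length ≤ 223 m, the
  union of a hexagonal tiling's perimeters and centre spokes) merged with
  classified roads (tarmac 75, loose surface 45, dry weather 40, motorable
  20 km/h; footpaths at walking speed). Each edge carries direction-specific
  pedestrian minutes and, on motorable classes, vehicular minutes; service
  areas and multimodal (walk + ride, free transfer) times come from
  direction-correct shortest paths.

On top of the engines:

* **coverage statistics** — cumulative % of population by 20-minute
  travel-time bands and at the 1-hour / 2-hour thresholds (zonal statistics
  over a census-rescaled gridded population), plus facility descriptive
  statistics: staffing classes (0 / 1 / ≥2 skilled birth attendants),
  delivery-caseload classes, medians/ranges, hospital share of deliveries.
* **scenario planner** — greedy maximal-coverage selection of a reduced set
  of delivery sites (hospitals locked in), coverage deltas, lost-access maps.
* **synthetic districts** — seeded generators for terrain, land use, water,
  clustered village population, road graphs and facility tables, so the whole
  pipeline runs end-to-end without any proprietary geodata. Two
  deterministic reference facility tables reproduce published district-level
  staffing/caseload marginals exactly.

## Command line

```sh
# generate a synthetic district
ruralaccess synth --seed 42 --scale 0.5 --out district/

# raster engine: minutes-to-nearest-facility surface
ruralaccess raster-access --dem district/dem.tif --landuse district/landuse.tif \
    --facilities district/facilities.csv --season dry --connectivity 16 \
    --out district/surface.tif

# network engine: per-node minutes over the mesh+roads graph
ruralaccess network-access --dem district/dem.tif --landuse district/landuse.tif \
    --roads district/roads.geojson --facilities district/facilities.csv \
    --mode pedestrian --side 223 --out district/node_times.csv

# population coverage by travel-time band
ruralaccess coverage --surface district/surface.tif \
    --population district/population.tif --out district/coverage.csv

# facility staffing/caseload summary
ruralaccess stats --facilities district/facilities.csv --out district/stats.csv

# delivery-site reduction scenario (40% fewer sites, hospitals kept)
ruralaccess scenario --dem district/dem.tif --landuse district/landuse.tif \
    --facilities district/facilities.csv --population district/population.tif \
    --reduce-frac 0.4 --out district/scenario.csv

# everything at once, with a JSON run manifest
ruralaccess run-all --seed 42 --scale 0.5 --out run/
```

A plain-text `key = value` config file (season, mode, band width, thresholds,
mesh side, connectivity, seed) can drive `run-all` via `--config`.

## Notes and caveats

* The multimodal mode assumes vehicles are available on every motorable road
  edge with zero waiting or transfer cost; it is an optimistic bound.
* Mesh edges never cross lakes/swamps, but road edges do (mapped roads imply
  bridges or ferries).
* Population resampling is mass-conserving area weighting, never
  interpolation, so coverage percentages neither invent nor lose people.
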