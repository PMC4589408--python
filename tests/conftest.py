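import numpy as np
import pytest

from ruralaccess.geodata_io import LandUseGrid, PopulationGrid, TerrainModel
from ruralaccess.speed_model import FrictionTable

ORIGIN = (500000.0, 9000000.0)
CRS = "EPSG:32736"


def make_terrain(elev, cell=90.0, mask=None):
    return TerrainModel(np.asarray(elev, dtype=float), cell, ORIGIN, CRS,
                        nodata_mask=mask)


def make_landuse(codes, cell=90.0, season="dry"):
    return LandUseGrid(np.asarray(codes, dtype=np.uint8), cell, ORIGIN, CRS,
                       season=season)


def flat_pair(shape=(12, 12), cell=90.0, elevation=1000.0, landuse=0):
    terrain = make_terrain(np.full(shape, elevation), cell)
    lu = make_landuse(np.full(shape, landuse), cell)
    return terrain, lu


def random_fixture(rng, shape=(20, 20), cell=90.0, barrier_frac=0.1,
                   relief=150.0, season=None):
    """Random terrain + mixed land use with barriers, for oracle comparison."""
    from scipy.ndimage import gaussian_filter

    z = gaussian_filter(rng.standard_normal(shape), 2.0) * relief
    codes = rng.choice([0, 1, 2], size=shape, p=[0.5, 0.3, 0.2]).astype(np.uint8)
    barrier = rng.random(shape) < barrier_frac
    codes[barrier] = 3
    season = season or rng.choice(["dry", "wet"])
    return (make_terrain(z, cell), make_landuse(codes, cell, season=season))


#: friction table with every coefficient 1 (for closed-form checks)
UNIT_FRICTION = FrictionTable(
    slope_coeffs=(1.0,) * 6,
    landuse_coeffs={s: {"open": 1.0, "bushy": 1.0, "forest": 1.0}
                    for s in ("dry", "wet")},
)


@pytest.fixture(scope="session")
def reference_district():
    """The packaged reference district at reduced scale (fast but non-trivial:
    2-hour coverage sits below 100%)."""
    from ruralaccess.synthetic_data import make_district, reference_district_spec

    spec = reference_district_spec(seed=42, scale=1.0)
    terrain, landuse, pop, villages, roads, facilities = make_district(spec)
    return {
        "spec": spec, "terrain": terrain, "landuse": landuse, "pop": pop,
        "villages": villages, "roads": roads, "facilities": facilities,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_population(data, cell=90.0):
    return PopulationGrid(np.asarray(data, dtype=float), cell, ORIGIN, CRS)
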