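import datetime as dt

import numpy as np
import pytest

from sympatric import synthetic_data as sd
from sympatric.camtrap_io import PhotoRecord, Species, Station


@pytest.fixture
def three_stations(tmp_path):
    """A 3-row station CSV: two DDF sites and one evergreen site."""
    path = tmp_path / "stations.csv"
    path.write_text(
        "station_id,survey_id,lat,lon,habitat,dist_water,"
        "deploy_start,deploy_end\n"
        "ST01,S1,13.0,107.0,DDF,1.2,2015-12-01,2016-02-28\n"
        "ST02,S1,13.1,107.1,ddf,0.5,2015-12-01,2016-02-28\n"
        "ST03,S1,13.2,107.2,Evergreen,2.0,2015-12-05,2016-02-20\n"
    )
    return path


@pytest.fixture
def five_records(tmp_path):
    path = tmp_path / "records.csv"
    path.write_text(
        "station_id,species,timestamp\n"
        "ST01,JUNGLE_CAT,2015-12-10T21:00:00\n"
        "ST01,Prionailurus bengalensis,2015-12-10T21:00:00\n"
        "ST02,LEOPARD_CAT,2015-12-15T03:30:00\n"
        "ST03,leopard cat,2016-01-02T22:10:00\n"
        "ST01,banteng,2016-01-20T08:00:00\n"
    )
    return path


def make_station(station_id="ST01", survey="S1", habitat="DDF",
                 start=dt.date(2015, 12, 1), days=90, dist_water=1.0):
    return Station(
        station_id=station_id, survey_id=survey, lat=13.0, lon=107.0,
        habitat=habitat, dist_water=dist_water, deploy_start=start,
        deploy_end=start + dt.timedelta(days=days - 1),
    )


def make_record(station="ST01", species=Species.JUNGLE_CAT,
                when="2015-12-10T21:00:00"):
    return PhotoRecord(
        station_id=station, species=species,
        timestamp=dt.datetime.fromisoformat(when),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Compact synthetic dataset shared by read-only tests."""
    cfg = sd.SyntheticConfig(n_sites=60, seed=123)
    return sd.gen_dataset(cfg)


@pytest.fixture
def rng():
    # fresh, identically seeded stream per test: statistical checks stay
    # deterministic regardless of test selection or order
    return np.random.default_rng(2026)
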