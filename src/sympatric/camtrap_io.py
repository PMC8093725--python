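"""Camera-trap tables, event independence, and occupancy detection histories.

Stations are camera deployments with habitat covariates; photo records carry
species and timestamp. Records of the same species at the same station are
collapsed to notionally independent events (>30 min apart), then aggregated
into per-species site x occasion binary detection matrices with an effort
matrix (functional days per 15-day occasion). Sites are
station-x-survey deployments; occasions tile each survey's span from its
earliest deployment date, with half-open day counting.
"""

from __future__ import annotations

import datetime as _dt
import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Species",
    "Station",
    "PhotoRecord",
    "DetectionHistory",
    "DEFAULT_SPECIES_ALIASES",
    "read_stations",
    "read_photo_records",
    "filter_independent_events",
    "build_detection_history",
    "naive_occupancy",
]


class Species(enum.Enum):
    JUNGLE_CAT = "JUNGLE_CAT"
    LEOPARD_CAT = "LEOPARD_CAT"
    OTHER = "OTHER"


#: Case-insensitive aliases applied when reading photo-record tables.
DEFAULT_SPECIES_ALIASES = {
    "jungle_cat": Species.JUNGLE_CAT,
    "jungle cat": Species.JUNGLE_CAT,
    "felis chaus": Species.JUNGLE_CAT,
    "leopard_cat": Species.LEOPARD_CAT,
    "leopard cat": Species.LEOPARD_CAT,
    "prionailurus bengalensis": Species.LEOPARD_CAT,
}


@dataclass(frozen=True)
class Station:
    station_id: str
    survey_id: str
    lat: float
    lon: float
    habitat: str  # "DDF" or "EVERGREEN"
    dist_water: float  # km
    deploy_start: _dt.date
    deploy_end: _dt.date

    def __post_init__(self) -> None:
        if self.habitat not in ("DDF", "EVERGREEN"):
            raise ValueError(f"station {self.station_id}: habitat {self.habitat!r}")
        if self.dist_water < 0:
            raise ValueError(f"station {self.station_id}: negative dist_water")
        if self.deploy_start > self.deploy_end:
            raise ValueError(f"station {self.station_id}: deploy_start > deploy_end")

    @property
    def site_key(self) -> tuple[str, str]:
        return (self.station_id, self.survey_id)


@dataclass(frozen=True)
class PhotoRecord:
    station_id: str
    species: Species
    timestamp: _dt.datetime
    in_deployment: bool = True  # False flags records outside the station window


@dataclass
class DetectionHistory:
    """Per-species site x occasion detection matrices plus effort.

    ``y`` maps species name to a float matrix with values {0, 1, nan}; nan
    marks occasions with zero effort (not surveyed). ``effort`` holds the
    functional days of each site within each occasion.
    """

    sites: list[tuple[str, str]]
    occasion_length: int
    y: dict[str, np.ndarray]
    effort: np.ndarray
    site_index: dict[tuple[str, str], int] = field(init=False)

    def __post_init__(self) -> None:
        self.site_index = {s: i for i, s in enumerate(self.sites)}
        n, t = self.effort.shape
        for sp, m in self.y.items():
            if m.shape != (n, t):
                raise ValueError(f"shape mismatch for {sp}")
            if np.any(np.isnan(m) != (self.effort == 0)):
                raise ValueError(f"{sp}: missing cells must coincide with zero effort")
            with np.errstate(invalid="ignore"):
                if np.any((m == 1) & (self.effort <= 0)):
                    raise ValueError(f"{sp}: detection with zero effort")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_occasions(self) -> int:
        return self.effort.shape[1]


_HABITAT_NORM = {"ddf": "DDF", "evergreen": "EVERGREEN", "ef": "EVERGREEN"}


def read_stations(path) -> list[Station]:
    """Read the station table (CSV) into validated ``Station`` objects.

    Required columns: station_id, survey_id, lat, lon, habitat, dist_water,
    deploy_start, deploy_end. Habitat strings are normalized
    case-insensitively; malformed rows raise with the offending row named.
    """
    df = pd.read_csv(path, dtype={"station_id": str, "survey_id": str})
    required = [
        "station_id", "survey_id", "lat", "lon",
        "habitat", "dist_water", "deploy_start", "deploy_end",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"station table missing columns: {missing}")
    stations = []
    for i, row in df.iterrows():
        try:
            habitat = _HABITAT_NORM.get(str(row["habitat"]).strip().lower())
            if habitat is None:
                raise ValueError(f"unrecognized habitat {row['habitat']!r}")
            stations.append(
                Station(
                    station_id=str(row["station_id"]),
                    survey_id=str(row["survey_id"]),
                    lat=float(row["lat"]),
                    lon=float(row["lon"]),
                    habitat=habitat,
                    dist_water=float(row["dist_water"]),
                    deploy_start=_parse_date(row["deploy_start"]),
                    deploy_end=_parse_date(row["deploy_end"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"station table row {i}: {exc}") from exc
    return stations


def _parse_date(value) -> _dt.date:
    ts = pd.Timestamp(value)
    if pd.isna(ts):
        raise ValueError(f"unparseable date {value!r}")
    return ts.date()


def read_photo_records(
    path,
    stations: list[Station] | None = None,
    aliases: dict[str, Species] | None = None,
) -> list[PhotoRecord]:
    """Read the photo-record table (CSV: station_id, species, timestamp).

    Species names are mapped through the (case-insensitive) alias table;
    unknown names become ``OTHER``. If ``stations`` is given, records at
    unknown stations raise, and records outside every deployment window of
    their station are kept but flagged ``in_deployment=False``.
    """
    df = pd.read_csv(path, dtype={"station_id": str, "species": str})
    required = ["station_id", "species", "timestamp"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"photo-record table missing columns: {missing}")
    alias = dict(DEFAULT_SPECIES_ALIASES)
    if aliases:
        alias.update({k.lower(): v for k, v in aliases.items()})

    windows: dict[str, list[tuple[_dt.date, _dt.date]]] = {}
    if stations is not None:
        for st in stations:
            windows.setdefault(st.station_id, []).append(
                (st.deploy_start, st.deploy_end)
            )
        unknown = sorted(set(df["station_id"]) - set(windows))
        if unknown:
            raise ValueError(f"photo records at unknown stations: {unknown}")

    records = []
    for i, row in df.iterrows():
        name = str(row["species"]).strip().lower()
        sp = alias.get(name)
        if sp is None:
            try:
                sp = Species(str(row["species"]).strip().upper())
            except ValueError:
                sp = Species.OTHER
        ts = pd.Timestamp(row["timestamp"])
        if pd.isna(ts):
            raise ValueError(f"photo-record row {i}: unparseable timestamp")
        ok = True
        if stations is not None:
            ok = any(
                a <= ts.date() <= b for a, b in windows[str(row["station_id"])]
            )
        records.append(
            PhotoRecord(
                station_id=str(row["station_id"]),
                species=sp,
                timestamp=ts.to_pydatetime(),
                in_deployment=ok,
            )
        )
    records.sort(key=lambda r: r.timestamp)
    return records


def filter_independent_events(
    records: list[PhotoRecord], window: float = 30.0
) -> list[PhotoRecord]:
    """Collapse photo bursts to independent events (> ``window`` min apart).

    Within each (station, species) stream sorted by time, a record is kept
    iff it is the first, or strictly more than ``window`` minutes after the
    last *kept* record. Suppression relative to the last kept record makes
    the filter idempotent. Output preserves overall chronology.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    delta = _dt.timedelta(minutes=window)
    last_kept: dict[tuple[str, Species], _dt.datetime] = {}
    kept = []
    for rec in sorted(records, key=lambda r: r.timestamp):
        key = (rec.station_id, rec.species)
        prev = last_kept.get(key)
        if prev is None or rec.timestamp - prev > delta:
            kept.append(rec)
            last_kept[key] = rec.timestamp
    return kept


def build_detection_history(
    events: list[PhotoRecord],
    stations: list[Station],
    occasion_length: int = 15,
) -> DetectionHistory:
    """Aggregate independent events into a detection history with effort.

    Occasions tile each survey's deployment span from the survey's earliest
    deploy_start. effort[i, t] counts the functional days of site i
    overlapping occasion t (half-open date intervals: start inclusive, end
    exclusive, with one day appended so a same-day deployment counts one
    day). y[i, t] is 1 if at least one event fell in occasion t, 0 if
    surveyed without an event, and nan where effort is zero.
    """
    if occasion_length <= 0:
        raise ValueError("occasion_length must be positive")
    if not stations:
        raise ValueError("no stations")

    sites = [st.site_key for st in stations]
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate station x survey deployments")
    survey_start: dict[str, _dt.date] = {}
    for st in stations:
        cur = survey_start.get(st.survey_id)
        if cur is None or st.deploy_start < cur:
            survey_start[st.survey_id] = st.deploy_start

    # half-open deployment interval [start, end + 1 day)
    n_occ = 0
    spans = []
    for st in stations:
        origin = survey_start[st.survey_id]
        start_day = (st.deploy_start - origin).days
        end_day = (st.deploy_end - origin).days + 1
        spans.append((start_day, end_day))
        n_occ = max(n_occ, -(-end_day // occasion_length))

    n = len(stations)
    effort = np.zeros((n, n_occ))
    for i, (s, e) in enumerate(spans):
        for t in range(n_occ):
            lo, hi = t * occasion_length, (t + 1) * occasion_length
            effort[i, t] = max(0, min(e, hi) - max(s, lo))

    species_names = [sp.name for sp in Species if sp is not Species.OTHER]
    y = {
        sp: np.where(effort > 0, 0.0, np.nan) for sp in species_names
    }

    # map events to sites by station id and timestamp within the window
    by_station: dict[str, list[int]] = {}
    for i, st in enumerate(stations):
        by_station.setdefault(st.station_id, []).append(i)
    unplaced = 0
    for ev in events:
        if ev.station_id not in by_station:
            raise ValueError(f"event at unknown station {ev.station_id!r}")
        placed = False
        for i in by_station[ev.station_id]:
            st = stations[i]
            if st.deploy_start <= ev.timestamp.date() <= st.deploy_end:
                origin = survey_start[st.survey_id]
                day = (ev.timestamp.date() - origin).days
                t = day // occasion_length
                if ev.species.name in y and effort[i, t] > 0:
                    y[ev.species.name][i, t] = 1.0
                placed = True
                break
        if not placed:
            unplaced += 1
    if unplaced:
        warnings.warn(
            f"{unplaced} event(s) outside every deployment window were ignored",
            stacklevel=2,
        )

    return DetectionHistory(
        sites=sites, occasion_length=occasion_length, y=y, effort=effort
    )


def naive_occupancy(history: DetectionHistory) -> dict[str, dict]:
    """Raw detection summaries per species (no detection correction).

    Counts sites with at least one detection, their proportion of all sites,
    and the number of detection-occasions (independent site x occasion
    records).
    """
    out = {}
    n = history.n_sites
    for sp, m in history.y.items():
        with np.errstate(invalid="ignore"):
            det = np.nansum(m, axis=1) > 0
        out[sp] = {
            "stations_detected": int(det.sum()),
            "proportion": float(det.sum() / n) if n else 0.0,
            "independent_records": int(np.nansum(m)),
        }
    return out
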