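"""Reading, writing and filtering of acoustic-telemetry detection logs.

Detections are carried as a pandas DataFrame with columns ``timestamp``
(timezone-aware UTC, second resolution), ``transmitter_id`` and
``receiver_id``, sorted by (transmitter_id, timestamp). Receiver and tag
metadata are small typed records (:class:`ReceiverSite`,
:class:`TagDeployment`) round-tripped through plain CSV.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DETECTION_COLUMNS = ["timestamp", "transmitter_id", "receiver_id"]


class Habitat(str, enum.Enum):
    clam_lease = "clam_lease"
    inlet = "inlet"
    lagoon = "lagoon"


class Species(str, enum.Enum):
    A_narinari = "A_narinari"
    R_bonasus = "R_bonasus"
    R_brasiliensis = "R_brasiliensis"
    Rhinoptera_unresolved = "Rhinoptera_unresolved"


@dataclasses.dataclass
class ReceiverSite:
    """A moored receiver station.

    ``general_location`` collapses habitat to the clam-lease vs other
    contrast used in the duration models; it is derived, not free.
    """

    receiver_id: str
    latitude: float
    longitude: float
    depth_m: float
    habitat: Habitat
    detection_radius_m: float = 200.0
    tide_lag_s: float = 0.0

    def __post_init__(self) -> None:
        self.habitat = Habitat(self.habitat)
        if self.detection_radius_m <= 0:
            raise ValueError("detection_radius_m must be positive")

    @property
    def general_location(self) -> str:
        return "clam_lease" if self.habitat is Habitat.clam_lease else "other"


_PING_INTERVALS = {"V13": (60.0, 180.0), "V16": (30.0, 90.0)}


@dataclasses.dataclass
class TagDeployment:
    """One transmitter implanted in one animal."""

    transmitter_id: str
    species: Species
    sex: str  # "F" | "M"
    disc_width_cm: float
    release_date: dt.date
    tag_model: str = "V13"
    weight_kg: float | None = None

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.disc_width_cm <= 0:
            raise ValueError("disc_width_cm must be positive")
        if self.tag_model not in _PING_INTERVALS:
            raise ValueError(f"unknown tag model {self.tag_model!r}")

    @property
    def ping_interval_s(self) -> tuple[float, float]:
        return _PING_INTERVALS[self.tag_model]


@dataclasses.dataclass
class CsvDialect:
    """Column mapping and parsing rules for a detection-log export."""

    timestamp_col: str = "datetime"
    transmitter_col: str = "transmitter"
    receiver_col: str = "receiver"
    datetime_format: str | None = None  # None -> flexible ISO-8601 parsing
    timezone: str = "UTC"  # zone of naive input timestamps
    known_receivers: Sequence[str] | None = None
    on_unknown_receiver: str = "warn"  # "warn" | "raise" | "ignore"


def read_detections(
    path: str | Path, dialect: CsvDialect | None = None, deduplicate: bool = True
) -> pd.DataFrame:
    """Read a detection-log CSV into the canonical detection frame.

    Unparseable timestamps raise a ``ValueError`` naming the offending line
    numbers (1-based, header = line 1). Unknown receivers are handled per
    ``dialect.on_unknown_receiver``. Extra columns are ignored.
    """
    dialect = dialect or CsvDialect()
    raw = pd.read_csv(path, dtype=str)
    for col in (dialect.timestamp_col, dialect.transmitter_col, dialect.receiver_col):
        if col not in raw.columns:
            raise ValueError(f"required column {col!r} not found in {path}")
    ts = pd.to_datetime(
        raw[dialect.timestamp_col], format=dialect.datetime_format, errors="coerce"
    )
    bad = ts.isna() | raw[dialect.transmitter_col].isna() | raw[dialect.receiver_col].isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise ValueError(f"unparseable detection records at lines {lines} of {path}")
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(dialect.timezone)
    ts = ts.dt.tz_convert("UTC").dt.floor("s")
    det = pd.DataFrame(
        {
            "timestamp": ts,
            "transmitter_id": raw[dialect.transmitter_col].astype(str),
            "receiver_id": raw[dialect.receiver_col].astype(str),
        }
    )
    if dialect.known_receivers is not None and dialect.on_unknown_receiver != "ignore":
        unknown = sorted(set(det["receiver_id"]) - set(dialect.known_receivers))
        if unknown:
            msg = f"unknown receiver ids in {path}: {unknown}"
            if dialect.on_unknown_receiver == "raise":
                raise ValueError(msg)
            import warnings

            warnings.warn(msg, stacklevel=2)
    if deduplicate:
        det = deduplicate_detections(det)
    return _sort_detections(det)


def _sort_detections(det: pd.DataFrame) -> pd.DataFrame:
    return det.sort_values(
        ["transmitter_id", "timestamp", "receiver_id"], kind="mergesort"
    ).reset_index(drop=True)


def deduplicate_detections(det: pd.DataFrame) -> pd.DataFrame:
    """Drop exact repeats of (timestamp, transmitter, receiver). Idempotent."""
    return _sort_detections(det.drop_duplicates(DETECTION_COLUMNS))


def write_detections(det: pd.DataFrame, path: str | Path) -> None:
    """Write detections as RFC-4180 CSV with ISO-8601 UTC timestamps."""
    out = det.copy()
    out["timestamp"] = (
        pd.to_datetime(out["timestamp"], utc=True)
        .dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    )
    out[DETECTION_COLUMNS].to_csv(path, index=False)


def filter_false_detections(
    det: pd.DataFrame, min_hits: int = 2, window_min: float = 60.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split detections into (kept, removed) by an isolation criterion.

    A detection is removed iff fewer than ``min_hits`` detections of the same
    transmitter (counting itself, at any receiver) fall within
    ``±window_min`` minutes of it. This is a reproducible stand-in for the
    manual screening of tag-collision false positives common in telemetry
    work; the parameters are part of the analysis configuration.
    """
    if det.empty:
        empty = det.iloc[0:0]
        return empty.copy(), empty.copy()
    det = _sort_detections(det)
    keep = np.zeros(len(det), dtype=bool)
    half_ns = int(round(window_min * 60 * 1e9))
    for _, grp in det.groupby("transmitter_id", sort=False):
        times = grp["timestamp"].astype("int64").to_numpy()
        lo = np.searchsorted(times, times - half_ns, side="left")
        hi = np.searchsorted(times, times + half_ns, side="right")
        keep[grp.index.to_numpy()] = (hi - lo) >= min_hits
    kept = det[keep].reset_index(drop=True)
    removed = det[~keep].reset_index(drop=True)
    return kept, removed


def study_window_clip(
    det: pd.DataFrame, start: dt.date, end: dt.date
) -> pd.DataFrame:
    """Keep detections with ``start <= t < end + 1 day`` (end date inclusive)."""
    if start > end:
        raise ValueError(f"inverted study window: {start} > {end}")
    t0 = pd.Timestamp(start, tz="UTC")
    t1 = pd.Timestamp(end, tz="UTC") + pd.Timedelta(days=1)
    ts = pd.to_datetime(det["timestamp"], utc=True)
    return det[(ts >= t0) & (ts < t1)].reset_index(drop=True)


# --- metadata CSV round-trips -------------------------------------------------

def write_receivers(sites: Iterable[ReceiverSite], path: str | Path) -> None:
    rows = []
    for s in sites:
        d = dataclasses.asdict(s)
        d["habitat"] = s.habitat.value
        d["general_location"] = s.general_location
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_receivers(path: str | Path) -> list[ReceiverSite]:
    df = pd.read_csv(path)
    fields = {f.name for f in dataclasses.fields(ReceiverSite)}
    return [
        ReceiverSite(**{k: v for k, v in row.items() if k in fields})
        for row in df.to_dict("records")
    ]


def write_tags(tags: Iterable[TagDeployment], path: str | Path) -> None:
    rows = []
    for t in tags:
        d = dataclasses.asdict(t)
        d["species"] = t.species.value
        d["release_date"] = t.release_date.isoformat()
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tags(path: str | Path) -> list[TagDeployment]:
    df = pd.read_csv(path)
    out = []
    for row in df.to_dict("records"):
        row = {k: v for k, v in row.items() if k != "ping_interval_s"}
        row["release_date"] = dt.date.fromisoformat(str(row["release_date"]))
        if "weight_kg" in row and pd.isna(row["weight_kg"]):
            row["weight_kg"] = None
        row["transmitter_id"] = str(row["transmitter_id"])
        out.append(TagDeployment(**row))
    return out


def tags_frame(tags: Iterable[TagDeployment]) -> pd.DataFrame:
    """Tag metadata as a DataFrame keyed by transmitter_id (for joins)."""
    rows = []
    for t in tags:
        d = dataclasses.asdict(t)
        d["species"] = t.species.value
        rows.append(d)
    return pd.DataFrame(rows)


def receivers_frame(sites: Iterable[ReceiverSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        d = dataclasses.asdict(s)
        d["habitat"] = s.habitat.value
        d["general_location"] = s.general_location
        rows.append(d)
    return pd.DataFrame(rows)
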