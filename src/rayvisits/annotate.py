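"""Covariate annotation: diel class, tide state, moon fraction, season.

Detections and visits are stamped with the covariates used by the count and
duration models. Times are stored UTC; diel and decimal-hour covariates are
computed on a configurable local clock (default America/New_York) because
day/night windows are local-clock conventions.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import astro
from .io import ReceiverSite

LOCAL_TZ = "America/New_York"

SEASONS = ("spring", "summer", "fall", "winter")
TIDE_STATES = ("High", "Incoming", "Low", "Outgoing")


@dataclasses.dataclass
class DielWindow:
    """Local-clock day/night boundaries; day = [day_start, night_start)."""

    day_start: dt.time = dt.time(7, 0, 0)
    night_start: dt.time = dt.time(19, 0, 0)
    timezone: str = LOCAL_TZ

    def __post_init__(self) -> None:
        if self.day_start == self.night_start:
            raise ValueError("day_start and night_start must differ")


def classify_diel(t, window: DielWindow | None = None):
    """Classify instants as "day" or "night" on the window's local clock.

    Vectorized: accepts a single datetime or an array-like; the window is
    exhaustive and exclusive over the 24-h cycle.
    """
    window = window or DielWindow()
    ts = pd.to_datetime(t, utc=True)
    scalar = not isinstance(ts, (pd.DatetimeIndex, pd.Series))
    idx = pd.DatetimeIndex([ts] if scalar else ts).tz_convert(window.timezone)
    secs = idx.hour * 3600 + idx.minute * 60 + idx.second
    lo = window.day_start.hour * 3600 + window.day_start.minute * 60 + window.day_start.second
    hi = window.night_start.hour * 3600 + window.night_start.minute * 60 + window.night_start.second
    if lo < hi:
        is_day = (secs >= lo) & (secs < hi)
    else:  # day window wraps midnight
        is_day = (secs >= lo) | (secs < hi)
    out = np.where(is_day, "day", "night")
    return str(out[0]) if scalar else out


def derive_diel_window(
    latitude: float,
    longitude: float,
    start: dt.date,
    end: dt.date,
    timezone: str = LOCAL_TZ,
) -> DielWindow:
    """Diel window from mean local sunrise/sunset over a date range.

    Means of the local clock times are rounded to the nearest hour, the
    convention used when a study adopts a single fixed day/night split.
    """
    if start > end:
        raise ValueError("empty date range")
    dates = pd.date_range(start, end, freq="D")
    rise_s, set_s = [], []
    for d in dates:
        r, s = astro.sunrise_sunset(d.date(), latitude, longitude)
        rl = pd.Timestamp(r).tz_convert(timezone)
        sl = pd.Timestamp(s).tz_convert(timezone)
        rise_s.append(rl.hour * 3600 + rl.minute * 60 + rl.second)
        set_s.append(sl.hour * 3600 + sl.minute * 60 + sl.second)

    def _round_hour(seconds: float) -> dt.time:
        h = int((seconds / 3600.0) + 0.5) % 24
        return dt.time(h, 0, 0)

    return DielWindow(
        day_start=_round_hour(float(np.mean(rise_s))),
        night_start=_round_hour(float(np.mean(set_s))),
        timezone=timezone,
    )


moon_fraction = astro.moon_fraction


def decimal_hour(t, timezone: str = LOCAL_TZ):
    """Local-clock decimal hour in [0, 24)."""
    ts = pd.to_datetime(t, utc=True)
    scalar = not isinstance(ts, (pd.DatetimeIndex, pd.Series))
    idx = pd.DatetimeIndex([ts] if scalar else ts).tz_convert(timezone)
    hours = idx.hour + idx.minute / 60.0 + idx.second / 3600.0
    hours = np.asarray(hours, dtype=float)
    return float(hours[0]) if scalar else hours


# --- tides -------------------------------------------------------------------

@dataclasses.dataclass
class TidalModel:
    """Tidal-phase propagation between a reference station and receivers.

    The tidal rate of movement (TRM) is the distance between two locations
    divided by the observed lag of the tidal state between them; each
    receiver's tide series is the reference prediction shifted by
    distance / TRM.
    """

    reference_station_lag_s: float = 8400.0  # 2 h 20 min
    reference_distance_m: float = 3698.0

    @property
    def trm_m_per_s(self) -> float:
        return compute_trm(self.reference_distance_m, self.reference_station_lag_s)

    def receiver_lag_s(self, distance_to_reference_m: float) -> float:
        return tide_offset(distance_to_reference_m, self.trm_m_per_s)


def compute_trm(d_m: float, delta_t_s: float) -> float:
    """Tidal rate of movement d / ΔT in m/s."""
    if delta_t_s <= 0:
        raise ValueError("delta_t_s must be positive")
    if d_m < 0:
        raise ValueError("distance must be nonnegative")
    return d_m / delta_t_s


def tide_offset(distance_m: float, trm_m_per_s: float) -> float:
    """Seconds by which a receiver's tide lags the reference station."""
    if trm_m_per_s <= 0:
        raise ValueError("trm must be positive")
    return distance_m / trm_m_per_s


def great_circle_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance in metres (shortest surface path)."""
    r = 6371008.8
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def receiver_tide_lags(
    sites: Sequence[ReceiverSite],
    reference_receiver: str,
    model: TidalModel | None = None,
) -> dict[str, float]:
    """Per-receiver tide lag (s) from great-circle distance to the reference."""
    model = model or TidalModel()
    ref = next(s for s in sites if s.receiver_id == reference_receiver)
    out = {}
    for s in sites:
        d = great_circle_m(ref.latitude, ref.longitude, s.latitude, s.longitude)
        out[s.receiver_id] = model.receiver_lag_s(d)
    return out


def assign_tide_state(
    t,
    extrema: pd.DataFrame,
    lag_s: float = 0.0,
    slack_fraction: float = 0.125,
):
    """Discretize the tidal cycle at ``t`` into High/Incoming/Low/Outgoing.

    ``extrema`` needs columns ``timestamp`` (tz-aware) and ``kind``
    ("H"/"L"), strictly alternating. The instant is first shifted by the
    receiver's lag (``t' = t - lag_s``). Within ``slack_fraction`` of a full
    cycle (2x the bracketing extremum gap) of a high or low extremum the
    state is High or Low; otherwise Incoming on the rising limb and Outgoing
    on the falling limb. The default 1/8-cycle slack band splits the cycle
    into four equal-duration states.
    """
    ex = extrema.sort_values("timestamp").reset_index(drop=True)
    kinds = ex["kind"].astype(str).str.upper().str[0].to_numpy()
    if len(ex) < 2 or not np.all(kinds[1:] != kinds[:-1]):
        raise ValueError("extrema must alternate H/L with at least two entries")
    ex_t = pd.to_datetime(ex["timestamp"], utc=True).astype("int64").to_numpy()

    ts = pd.to_datetime(t, utc=True)
    scalar = not isinstance(ts, (pd.DatetimeIndex, pd.Series))
    idx = pd.DatetimeIndex([ts] if scalar else ts)
    tq = idx.astype("int64").to_numpy() - int(round(lag_s * 1e9))

    pos = np.searchsorted(ex_t, tq, side="right")
    if np.any(pos == 0) or np.any(pos >= len(ex_t)):
        raise ValueError("instant (after lag shift) outside tide extrema coverage")
    prev_t, next_t = ex_t[pos - 1], ex_t[pos]
    gap = next_t - prev_t
    slack = (2.0 * gap) * slack_fraction  # fraction of the full cycle
    prev_kind = kinds[pos - 1]
    near_prev = (tq - prev_t) <= slack
    near_next = (next_t - tq) < slack
    state = np.where(prev_kind == "L", "Incoming", "Outgoing")
    state = np.where(near_prev, np.where(prev_kind == "H", "High", "Low"), state)
    state = np.where(
        near_next, np.where(prev_kind == "H", "Low", "High"), state
    )
    return str(state[0]) if scalar else state


# --- season / study year -----------------------------------------------------

def assign_season(d):
    """Astronomical season of a date (boundaries at equinoxes/solstices)."""
    dates = pd.to_datetime(d)
    scalar = not isinstance(dates, (pd.DatetimeIndex, pd.Series))
    idx = pd.DatetimeIndex([dates] if scalar else dates)
    out = []
    for ts in idx:
        day = ts.date()
        vern, summ, autu, wint = astro.season_boundaries(day.year)
        if day < vern:
            out.append("winter")
        elif day < summ:
            out.append("spring")
        elif day < autu:
            out.append("summer")
        elif day < wint:
            out.append("fall")
        else:
            out.append("winter")
    return out[0] if scalar else np.array(out)


def assign_study_year(
    d,
    year1_start: dt.date = dt.date(2017, 6, 1),
    n_years: int = 2,
):
    """Map dates to study years Y1, Y2, ... (12-month blocks from the start)."""
    dates = pd.to_datetime(d)
    scalar = not isinstance(dates, (pd.DatetimeIndex, pd.Series))
    idx = pd.DatetimeIndex([dates] if scalar else dates)
    out = []
    for ts in idx:
        day = ts.date()
        for k in range(n_years):
            lo = dt.date(year1_start.year + k, year1_start.month, year1_start.day)
            hi = dt.date(year1_start.year + k + 1, year1_start.month, year1_start.day)
            if lo <= day < hi:
                out.append(f"Y{k + 1}")
                break
        else:
            raise ValueError(f"date {day} outside the study window")
    return out[0] if scalar else np.array(out)


# --- joined annotation -------------------------------------------------------

def annotate_detections(
    det: pd.DataFrame, window: DielWindow | None = None
) -> pd.DataFrame:
    """Add diel class and local date columns to a detection frame."""
    out = det.copy()
    window = window or DielWindow()
    out["diel"] = classify_diel(out["timestamp"], window)
    out["date_local"] = (
        pd.to_datetime(out["timestamp"], utc=True)
        .dt.tz_convert(window.timezone)
        .dt.date
    )
    return out


def annotate_visits(
    visits: pd.DataFrame,
    receivers: Sequence[ReceiverSite],
    env: pd.DataFrame,
    tide_extrema: pd.DataFrame,
    tide_lags: dict[str, float] | None = None,
    window: DielWindow | None = None,
    env_tolerance: pd.Timedelta = pd.Timedelta(minutes=30),
) -> pd.DataFrame:
    """Join model covariates onto a visit table (one row per visit).

    Adds diel, decimal hour, moon fraction, tide state (with per-receiver
    lag), season, study year, general location and nearest-in-time
    environmental covariates (within ``env_tolerance``; unmatched visits
    keep NaN and are expected to be dropped by the model layer).
    """
    window = window or DielWindow()
    tide_lags = tide_lags or {}
    out = visits.copy()
    start = pd.to_datetime(out["start"], utc=True)
    out["diel"] = classify_diel(start, window)
    out["decimal_hour"] = decimal_hour(start, window.timezone)
    out["moon_fraction"] = astro.moon_fraction(start)
    out["season"] = assign_season(start.dt.tz_convert(window.timezone).dt.date)
    loc = {s.receiver_id: s.general_location for s in receivers}
    out["general_location"] = out["receiver_id"].map(loc)
    tide = np.empty(len(out), dtype=object)
    for rid, grp in out.groupby("receiver_id"):
        tide[grp.index.to_numpy()] = assign_tide_state(
            start.loc[grp.index], tide_extrema, lag_s=tide_lags.get(rid, 0.0)
        )
    out["tide_state"] = tide

    envs = env.sort_values("timestamp").reset_index(drop=True)
    envs["timestamp"] = pd.to_datetime(envs["timestamp"], utc=True)
    merged = pd.merge_asof(
        out.assign(_start=start).sort_values("_start"),
        envs,
        left_on="_start",
        right_on="timestamp",
        direction="nearest",
        tolerance=env_tolerance,
        suffixes=("", "_env"),
    ).drop(columns=["_start", "timestamp", "timestamp_env"], errors="ignore")
    merged = merged.sort_values(["transmitter_id", "start"]).reset_index(drop=True)
    return merged
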