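"""Synthetic acoustic-telemetry generator with known ground truth.

Emulates a two-species, six-receiver estuarine array: animals move among
receiver sites (and an off-array "absent" state) in continuous time with
diel-dependent site preferences; occupancy-bout durations are Gamma with
log-linear covariate effects (hour-of-day harmonic, moon fraction, clam
lease, tide state); tags transmit at uniform random intervals and each
transmission during a bout is logged by that site's receiver with a fixed
detection probability. Environmental and tide series are generated
alongside, with oxygen saturation built collinear with temperature so the
collinearity screen has something to catch. Everything is deterministic
under the seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import astro
from .annotate import DielWindow, assign_season, classify_diel
from .io import ReceiverSite, TagDeployment, write_detections

DEFAULT_SITES = [
    ReceiverSite("IR16", 27.8380, -80.4890, 2.0, "lagoon"),
    ReceiverSite("SCLN", 27.8830, -80.4930, 1.5, "clam_lease"),
    ReceiverSite("SCLS", 27.8200, -80.4750, 1.5, "clam_lease"),
    ReceiverSite("SINJ", 27.8620, -80.4450, 4.8, "inlet"),
    ReceiverSite("SISO", 27.8608, -80.4520, 2.1, "inlet"),
    ReceiverSite("SIWP", 27.8595, -80.4600, 2.1, "inlet"),
]


@dataclasses.dataclass
class DurationEffects:
    """Log-linear covariate effects on the Gamma mean of site-bout duration."""

    hour_amplitude: float = 0.35  # cosine harmonic on local hour
    hour_peak: float = 10.0  # local hour of longest bouts
    moon_coef: float = 0.4  # per unit illuminated fraction (centred)
    lease_coef: float = 0.25  # clam-lease sites vs others
    tide_coefs: dict = dataclasses.field(
        default_factory=lambda: {"High": 0.0, "Incoming": 0.1, "Low": -0.1, "Outgoing": 0.1}
    )


@dataclasses.dataclass
class SpeciesSimConfig:
    species: str
    n_tags: int
    tag_model: str
    day_site_weights: dict
    night_site_weights: dict
    absent_weight_day: float = 6.0
    absent_weight_night: float = 6.0
    summer_absent_multiplier: float = 1.0
    mean_bout_min: float = 30.0
    bout_shape: float = 1.5
    mean_absence_min: float = 3000.0
    absence_shape: float = 0.5
    effects: DurationEffects = dataclasses.field(default_factory=DurationEffects)
    disc_width_range_cm: tuple = (80.0, 190.0)


def default_species() -> list[SpeciesSimConfig]:
    """Two species qualitatively mirroring the study system.

    Eagle rays are inlet-heavy, day-active and present year-round; cownose
    rays are lagoon-heavy, more nocturnal, with reduced summer presence.
    No quantitative claim is attached to these defaults.
    """
    eagle = SpeciesSimConfig(
        species="A_narinari",
        n_tags=20,
        tag_model="V16",
        day_site_weights={"SINJ": 4.0, "SISO": 2.2, "SIWP": 0.7, "IR16": 0.8, "SCLN": 0.35, "SCLS": 0.2},
        night_site_weights={"SINJ": 2.0, "SISO": 1.2, "SIWP": 0.4, "IR16": 1.8, "SCLN": 0.8, "SCLS": 0.4},
        disc_width_range_cm=(65.0, 196.0),
    )
    cownose = SpeciesSimConfig(
        species="R_bonasus",
        n_tags=18,
        tag_model="V13",
        day_site_weights={"IR16": 1.2, "SCLN": 1.0, "SCLS": 0.7, "SINJ": 0.5, "SISO": 0.7, "SIWP": 0.3},
        night_site_weights={"IR16": 2.0, "SCLN": 1.5, "SCLS": 1.0, "SINJ": 0.4, "SISO": 0.4, "SIWP": 0.2},
        summer_absent_multiplier=4.0,
        mean_bout_min=25.0,
        mean_absence_min=4000.0,
        disc_width_range_cm=(46.6, 104.0),
    )
    return [eagle, cownose]


@dataclasses.dataclass
class SimConfig:
    seed: int = 0
    start: dt.date = dt.date(2017, 6, 1)
    end: dt.date = dt.date(2019, 5, 31)
    sites: Sequence[ReceiverSite] = dataclasses.field(default_factory=lambda: list(DEFAULT_SITES))
    species: Sequence[SpeciesSimConfig] = dataclasses.field(default_factory=default_species)
    detection_prob: float = 0.7
    false_positive_per_day: float = 0.5  # spurious array-wide detections/day
    env_freq: str = "1h"
    temp_mean_c: float = 25.0
    temp_seasonal_amp_c: float = 5.0
    tidal_period_h: float = 12.4206

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")


@dataclasses.dataclass
class SimResult:
    config: SimConfig
    receivers: list
    tags: list
    env: pd.DataFrame
    tide_extrema: pd.DataFrame
    bouts: pd.DataFrame  # ground-truth occupancy bouts
    transmissions: pd.DataFrame  # every ping emitted during a bout
    detections: pd.DataFrame  # logged pings (incl. spurious)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_receivers, write_tags

        write_receivers(self.receivers, out / "receivers.csv")
        write_tags(self.tags, out / "tags.csv")
        self.env.to_csv(out / "env.csv", index=False)
        self.tide_extrema.to_csv(out / "tides.csv", index=False)
        self.bouts.to_csv(out / "truth_bouts.csv", index=False)
        write_detections(self.detections, out / "detections.csv")


# --- environment --------------------------------------------------------------

def simulate_environment(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Hourly water-quality series and tide-extrema table.

    Temperature is a seasonal sinusoid with AR(1) noise; oxygen saturation
    is constructed collinear with temperature (r > 0.9); dissolved oxygen
    carries only a weak temperature dependence. Tide extrema alternate H/L
    at half the principal lunar semidiurnal period with small timing jitter.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    t0 = pd.Timestamp(cfg.start, tz="UTC")
    t1 = pd.Timestamp(cfg.end, tz="UTC") + pd.Timedelta(days=1)
    idx = pd.date_range(t0, t1, freq=cfg.env_freq, inclusive="left")
    n = len(idx)
    doy = idx.dayofyear.to_numpy()
    seasonal = np.sin(2 * np.pi * (doy - 120) / 365.25)
    ar = np.empty(n)
    eps = rng.normal(0, 0.35, n)
    ar[0] = eps[0]
    for i in range(1, n):
        ar[i] = 0.95 * ar[i - 1] + eps[i]
    temp = cfg.temp_mean_c + cfg.temp_seasonal_amp_c * seasonal + ar
    salinity = 28.0 + 2.0 * np.sin(2 * np.pi * (doy - 30) / 365.25) + rng.normal(0, 0.8, n)
    do = 7.0 - 0.12 * (temp - cfg.temp_mean_c) + rng.normal(0, 0.5, n)
    o2_sat = 85.0 + 2.6 * (temp - cfg.temp_mean_c) + rng.normal(0, 0.6, n)
    env = pd.DataFrame(
        {
            "timestamp": idx,
            "water_temp_c": temp,
            "salinity": salinity,
            "do_mg_l": do,
            "o2_sat_pct": o2_sat,
            "moon_fraction": astro.moon_fraction(idx),
        }
    )

    half_period_h = cfg.tidal_period_h / 2.0
    times = []
    kinds = []
    t = t0 - pd.Timedelta(hours=rng.uniform(0, half_period_h))
    kind = "H"
    while t < t1 + pd.Timedelta(hours=13):
        times.append(t)
        kinds.append(kind)
        t = t + pd.Timedelta(hours=half_period_h * (1 + rng.normal(0, 0.02)))
        kind = "L" if kind == "H" else "H"
    heights = np.where(np.array(kinds) == "H", 0.45, 0.05) + rng.normal(0, 0.02, len(kinds))
    tides = pd.DataFrame({"timestamp": times, "kind": kinds, "height_m": heights})
    return env, tides


# --- movement -----------------------------------------------------------------

def _tide_state_fast(t_ns: int, ex_ns: np.ndarray, ex_kinds: np.ndarray) -> str:
    pos = np.searchsorted(ex_ns, t_ns, side="right")
    if pos == 0 or pos >= len(ex_ns):
        return "High"
    prev_t, next_t = ex_ns[pos - 1], ex_ns[pos]
    gap = next_t - prev_t
    slack = gap / 4.0
    pk = ex_kinds[pos - 1]
    if t_ns - prev_t <= slack:
        return "High" if pk == "H" else "Low"
    if next_t - t_ns < slack:
        return "Low" if pk == "H" else "High"
    return "Incoming" if pk == "L" else "Outgoing"


def simulate_movement(
    cfg: SimConfig,
    env: pd.DataFrame,
    tides: pd.DataFrame,
    window: DielWindow | None = None,
) -> tuple[pd.DataFrame, list]:
    """Ground-truth occupancy bouts for every tag, plus tag metadata.

    Each tag alternates between off-array absences and site bouts. Sites
    are chosen by diel-dependent weights; bout durations are Gamma with
    mean exp-linked to the covariates at bout start, so downstream duration
    models have a recoverable signal.
    """
    window = window or DielWindow()
    site_ids = [s.receiver_id for s in cfg.sites]
    lease = {s.receiver_id: s.general_location == "clam_lease" for s in cfg.sites}
    ex_ns = pd.to_datetime(tides["timestamp"], utc=True).astype("int64").to_numpy()
    ex_kinds = tides["kind"].astype(str).str.upper().str[0].to_numpy()
    env_ns = pd.to_datetime(env["timestamp"], utc=True).astype("int64").to_numpy()
    moon = env["moon_fraction"].to_numpy()

    t0 = pd.Timestamp(cfg.start, tz="UTC")
    t1 = pd.Timestamp(cfg.end, tz="UTC") + pd.Timedelta(days=1)
    rows = []
    tags: list[TagDeployment] = []
    tag_counter = 0
    for sp in cfg.species:
        if not (sp.day_site_weights or sp.night_site_weights):
            raise ValueError("species has no site weights")
        for k in range(sp.n_tags):
            tag_counter += 1
            tid = f"{sp.species[:2].upper()}{tag_counter:03d}"
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 2, tag_counter])
            )
            tags.append(
                TagDeployment(
                    transmitter_id=tid,
                    species=sp.species,
                    sex="F" if rng.random() < 0.5 else "M",
                    disc_width_cm=float(rng.uniform(*sp.disc_width_range_cm)),
                    release_date=cfg.start,
                    tag_model=sp.tag_model,
                )
            )
            t = t0 + pd.Timedelta(minutes=float(rng.exponential(sp.mean_absence_min / 2)))
            bout_id = 0
            while t < t1:
                is_day = classify_diel(t, window) == "day"
                weights = dict(sp.day_site_weights if is_day else sp.night_site_weights)
                absent_w = sp.absent_weight_day if is_day else sp.absent_weight_night
                if assign_season(t.date()) == "summer":
                    absent_w *= sp.summer_absent_multiplier
                names = [s for s in site_ids if weights.get(s, 0) > 0] + ["absent"]
                w = np.array([weights.get(s, 0.0) for s in names[:-1]] + [absent_w])
                if w.sum() <= 0:
                    raise ValueError("degenerate all-zero movement weights")
                choice = rng.choice(names, p=w / w.sum())
                if choice == "absent":
                    dur_min = rng.gamma(
                        sp.absence_shape, sp.mean_absence_min / sp.absence_shape
                    )
                    t = t + pd.Timedelta(minutes=float(dur_min))
                    continue
                # covariates at bout start
                h_local = (
                    t.tz_convert(window.timezone).hour
                    + t.tz_convert(window.timezone).minute / 60.0
                )
                i_env = min(
                    np.searchsorted(env_ns, t.value), len(env_ns) - 1
                )
                mf = moon[i_env]
                tide_state = _tide_state_fast(t.value, ex_ns, ex_kinds)
                eff = sp.effects
                log_mult = (
                    eff.hour_amplitude * np.cos(2 * np.pi * (h_local - eff.hour_peak) / 24.0)
                    + eff.moon_coef * (mf - 0.5)
                    + (eff.lease_coef if lease[choice] else 0.0)
                    + eff.tide_coefs.get(tide_state, 0.0)
                )
                mean = sp.mean_bout_min * float(np.exp(log_mult))
                dur_min = float(rng.gamma(sp.bout_shape, mean / sp.bout_shape))
                dur_min = max(dur_min, 0.05)
                end = min(t + pd.Timedelta(minutes=dur_min), t1)
                bout_id += 1
                rows.append(
                    {
                        "transmitter_id": tid,
                        "bout_id": f"{tid}-{bout_id}",
                        "site": choice,
                        "arrival": t,
                        "departure": end,
                        "duration_min": (end - t).total_seconds() / 60.0,
                        "hour_local": h_local,
                        "moon_fraction": mf,
                        "tide_state": tide_state,
                        "is_clam_lease": lease[choice],
                        "true_mean_min": mean,
                    }
                )
                t = end
    bouts = pd.DataFrame(rows)
    if not bouts.empty:
        bouts = bouts.sort_values(["transmitter_id", "arrival"]).reset_index(drop=True)
    return bouts, tags


# --- detections ---------------------------------------------------------------

def simulate_detections(
    bouts: pd.DataFrame, tags: list, cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transmissions during bouts and the thinned detection log.

    Inter-ping gaps are uniform on the tag model's interval; each ping is
    logged by the occupied site's receiver with ``detection_prob``.
    Spurious tag-collision detections are added at a configurable Poisson
    rate with random tag and receiver ids, then the log is sorted like a
    receiver download.
    """
    interval = {t.transmitter_id: t.ping_interval_s for t in tags}
    tx_rows = []
    for tid, grp in bouts.groupby("transmitter_id", sort=True):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 3, zlib.crc32(tid.encode()) % (2**31)])
        )
        lo, hi = interval[tid]
        for bout in grp.itertuples():
            start_ns = bout.arrival.value
            end_ns = bout.departure.value
            dur_s = (end_ns - start_ns) / 1e9
            n_max = int(dur_s / lo) + 2
            gaps = rng.uniform(lo, hi, n_max)
            times = start_ns + np.cumsum(np.r_[rng.uniform(0, (lo + hi) / 2), gaps]) * 1e9
            times = times[times <= end_ns]
            for t_ns in times:
                tx_rows.append((tid, bout.site, int(t_ns), bout.bout_id))
    transmissions = pd.DataFrame(
        tx_rows, columns=["transmitter_id", "receiver_id", "t_ns", "bout_id"]
    )
    if not transmissions.empty:
        transmissions["timestamp"] = pd.to_datetime(
            transmissions["t_ns"], utc=True
        ).dt.floor("s")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    if transmissions.empty or cfg.detection_prob == 0:
        detected = transmissions.iloc[0:0]
    else:
        keep = rng.random(len(transmissions)) < cfg.detection_prob
        detected = transmissions[keep]
    det = detected[["timestamp", "transmitter_id", "receiver_id"]].copy() if len(detected) else pd.DataFrame(columns=["timestamp", "transmitter_id", "receiver_id"])

    n_days = (pd.Timestamp(cfg.end) - pd.Timestamp(cfg.start)).days + 1
    n_fp = rng.poisson(cfg.false_positive_per_day * n_days)
    if n_fp > 0 and tags:
        t0 = pd.Timestamp(cfg.start, tz="UTC").value
        t1 = pd.Timestamp(cfg.end, tz="UTC").value + 86_400_000_000_000
        fp = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(
                    rng.integers(t0, t1, n_fp), utc=True
                ).floor("s"),
                "transmitter_id": rng.choice([t.transmitter_id for t in tags], n_fp),
                "receiver_id": rng.choice([s.receiver_id for s in cfg.sites], n_fp),
            }
        )
        det = pd.concat([det, fp], ignore_index=True)
    det = (
        det.drop_duplicates(["timestamp", "transmitter_id", "receiver_id"])
        .sort_values(["transmitter_id", "timestamp", "receiver_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return det, transmissions.drop(columns=["t_ns"], errors="ignore")


def truth_visit_table(
    transmissions: pd.DataFrame, timeout_min: float = 17.1, min_detections: int = 2
) -> pd.DataFrame:
    """Visits an ideal (probability-1) detector would report.

    Scans each transmitter's full transmission sequence chronologically with
    the same inclusive-gap / receiver-change rule as the extractor
    (implemented independently as a plain loop). Same-site occupancy bouts
    separated by less than the time-out are indistinguishable to any
    detector and therefore merge into one expected visit.
    """
    rows = []
    timeout_ns = timeout_min * 60e9
    if transmissions.empty:
        return pd.DataFrame(
            columns=["transmitter_id", "receiver_id", "start", "end", "duration_min", "n_detections"]
        )
    tr = transmissions.copy()
    tr["t_ns"] = pd.to_datetime(tr["timestamp"], utc=True).astype("int64")
    for tid, grp in tr.groupby("transmitter_id", sort=True):
        grp = grp.sort_values(["t_ns", "receiver_id"])
        times = grp["t_ns"].to_numpy()
        sites = grp["receiver_id"].to_numpy()
        run = [times[0]]
        site = sites[0]
        for t_ns, s in zip(times[1:], sites[1:]):
            if s != site or t_ns - run[-1] > timeout_ns:
                if len(run) >= min_detections:
                    rows.append((tid, site, run[0], run[-1], len(run)))
                run = [t_ns]
                site = s
            else:
                run.append(t_ns)
        if len(run) >= min_detections:
            rows.append((tid, site, run[0], run[-1], len(run)))
    out = pd.DataFrame(
        rows, columns=["transmitter_id", "receiver_id", "start_ns", "end_ns", "n_detections"]
    )
    out["start"] = pd.to_datetime(out["start_ns"], utc=True)
    out["end"] = pd.to_datetime(out["end_ns"], utc=True)
    out["duration_min"] = (out["end_ns"] - out["start_ns"]) / 60e9
    out = out.drop(columns=["start_ns", "end_ns"])
    return out.sort_values(["transmitter_id", "start"]).reset_index(drop=True)[
        ["transmitter_id", "receiver_id", "start", "end", "duration_min", "n_detections"]
    ]


def simulate(cfg: SimConfig | None = None) -> SimResult:
    """Run the full generator: environment, movement, transmissions, log."""
    cfg = cfg or SimConfig()
    env, tides = simulate_environment(cfg)
    bouts, tags = simulate_movement(cfg, env, tides)
    detections, transmissions = simulate_detections(bouts, tags, cfg)
    return SimResult(
        config=cfg,
        receivers=list(cfg.sites),
        tags=tags,
        env=env,
        tide_extrema=tides,
        bouts=bouts,
        transmissions=transmissions,
        detections=detections,
    )
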