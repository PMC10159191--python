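import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from rayvisits import simdata

hyp_settings.register_profile("repro", derandomize=True)
hyp_settings.load_profile("repro")


def make_detections(records):
    """Detection frame from (iso_timestamp, transmitter, receiver) tuples."""
    df = pd.DataFrame(records, columns=["timestamp", "transmitter_id", "receiver_id"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df.sort_values(["transmitter_id", "timestamp", "receiver_id"]).reset_index(
        drop=True
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 30-day, 2x3-tag simulation reused by annotation/pipeline tests."""
    species = simdata.default_species()
    for s in species:
        s.n_tags = 3
    cfg = simdata.SimConfig(
        seed=11, start=dt.date(2017, 7, 1), end=dt.date(2017, 7, 30), species=species
    )
    return simdata.simulate(cfg)


@pytest.fixture(scope="session")
def synthetic_tide_extrema():
    """Clean sinusoidal-tide extrema: strict 6.21-h alternation over 60 days."""
    times = pd.date_range("2017-06-01", periods=240, freq="372.6min", tz="UTC")
    kinds = ["H", "L"] * 120
    return pd.DataFrame({"timestamp": times, "kind": kinds[: len(times)]})
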