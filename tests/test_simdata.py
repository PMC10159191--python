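import datetime as dt

import numpy as np
import pandas as pd
import pytest

from rayvisits import VisitParams, extract_visits, filter_false_detections
from rayvisits import simdata
from rayvisits.simdata import (
    SimConfig,
    SpeciesSimConfig,
    simulate,
    simulate_environment,
    truth_visit_table,
)


def _one_species(**kw):
    defaults = dict(
        species="A_narinari",
        n_tags=2,
        tag_model="V16",
        day_site_weights={"SINJ": 2.0, "SCLN": 1.0},
        night_site_weights={"IR16": 2.0, "SCLN": 1.0},
    )
    defaults.update(kw)
    return SpeciesSimConfig(**defaults)


class TestEnvironment:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=3, end=dt.date(2017, 6, 20))
        e1, t1 = simulate_environment(cfg)
        e2, t2 = simulate_environment(cfg)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_extrema_alternate_strictly(self):
        cfg = SimConfig(seed=3, end=dt.date(2017, 7, 31))
        _, tides = simulate_environment(cfg)
        kinds = tides["kind"].to_numpy()
        assert np.all(kinds[1:] != kinds[:-1])

    def test_o2_sat_collinear_with_temperature(self):
        cfg = SimConfig(seed=3, end=dt.date(2017, 8, 31))
        env, _ = simulate_environment(cfg)
        assert env["water_temp_c"].corr(env["o2_sat_pct"]) > 0.9


class TestMovement:
    def test_diel_preference_expressed(self):
        sp = _one_species(
            day_site_weights={"SINJ": 5.0, "SISO": 3.0},
            night_site_weights={"IR16": 5.0, "SCLN": 3.0},
            n_tags=4,
        )
        sp.absent_weight_day = sp.absent_weight_night = 2.0
        sp.mean_absence_min = 600.0
        cfg = SimConfig(seed=9, end=dt.date(2017, 7, 31), species=[sp])
        res = simulate(cfg)
        bouts = res.bouts
        from rayvisits import classify_diel

        diel = np.array([classify_diel(t) for t in bouts["arrival"]])
        day_bouts = bouts[diel == "day"]
        inlet_time = day_bouts.loc[
            day_bouts["site"].isin(["SINJ", "SISO", "SIWP"]), "duration_min"
        ].sum()
        assert inlet_time / day_bouts["duration_min"].sum() > 0.7

    def test_single_site_config_stays_there(self):
        sp = _one_species(
            day_site_weights={"SINJ": 1.0}, night_site_weights={"SINJ": 1.0}
        )
        sp.absent_weight_day = sp.absent_weight_night = 0.0
        cfg = SimConfig(seed=2, end=dt.date(2017, 6, 10), species=[sp])
        res = simulate(cfg)
        assert set(res.bouts["site"]) == {"SINJ"}

    def test_degenerate_zero_weights_raise(self):
        sp = _one_species(day_site_weights={}, night_site_weights={})
        sp.absent_weight_day = sp.absent_weight_night = 0.0
        cfg = SimConfig(seed=2, end=dt.date(2017, 6, 5), species=[sp])
        with pytest.raises(ValueError):
            simulate(cfg)

    def test_bout_mean_tracks_configured_gamma(self):
        # with all covariate effects off, bout durations average to the base
        sp = _one_species(n_tags=10)
        sp.effects = simdata.DurationEffects(
            hour_amplitude=0.0, moon_coef=0.0, lease_coef=0.0,
            tide_coefs={},
        )
        sp.mean_bout_min = 40.0
        sp.absent_weight_day = sp.absent_weight_night = 1.0
        sp.mean_absence_min = 300.0
        cfg = SimConfig(seed=5, end=dt.date(2017, 8, 31), species=[sp])
        res = simulate(cfg)
        # exclude window-truncated bouts
        full = res.bouts[res.bouts["departure"] < pd.Timestamp("2017-09-01", tz="UTC")]
        assert len(full) > 2000
        assert full["duration_min"].mean() == pytest.approx(40.0, rel=0.05)


class TestDetections:
    def test_prob_one_fixed_interval_regular_pings(self):
        sp = _one_species(tag_model="V16", n_tags=1)
        cfg = SimConfig(
            seed=4, end=dt.date(2017, 6, 10), species=[sp],
            detection_prob=1.0, false_positive_per_day=0.0,
        )
        res = simulate(cfg)
        gaps = (
            res.transmissions.sort_values(["bout_id", "timestamp"])
            .groupby("bout_id")["timestamp"].diff().dropna().dt.total_seconds()
        )
        lo, hi = 30.0, 90.0
        assert gaps.between(lo - 1, hi + 1).all()
        # prob=1: every transmission logged
        assert len(res.detections) == len(
            res.transmissions.drop_duplicates(["timestamp", "transmitter_id", "receiver_id"])
        )

    def test_prob_zero_empty_log(self):
        sp = _one_species(n_tags=1)
        cfg = SimConfig(
            seed=4, end=dt.date(2017, 6, 10), species=[sp],
            detection_prob=0.0, false_positive_per_day=0.0,
        )
        res = simulate(cfg)
        assert res.detections.empty

    def test_thinning_rate(self):
        sp = _one_species(n_tags=4)
        cfg = SimConfig(
            seed=4, end=dt.date(2017, 7, 31), species=[sp],
            detection_prob=0.6, false_positive_per_day=0.0,
        )
        res = simulate(cfg)
        frac = len(res.detections) / len(res.transmissions)
        assert frac == pytest.approx(0.6, abs=0.03)

    def test_detection_csv_byte_identical_under_seed(self, tmp_path):
        sp = _one_species(n_tags=2)
        cfg = SimConfig(seed=13, end=dt.date(2017, 6, 15), species=[sp])
        a, b = tmp_path / "a", tmp_path / "b"
        simulate(cfg).write(a)
        simulate(cfg).write(b)
        assert (a / "detections.csv").read_bytes() == (b / "detections.csv").read_bytes()


class TestTruthVisits:
    def test_short_bout_without_two_pings_excluded(self):
        tr = pd.DataFrame(
            {
                "transmitter_id": ["A"],
                "receiver_id": ["SINJ"],
                "bout_id": ["A-1"],
                "timestamp": [pd.Timestamp("2017-06-01", tz="UTC")],
            }
        )
        assert truth_visit_table(tr).empty

    def test_hour_bout_yields_one_visit_within_two_gaps(self):
        # 60-min bout, pings every <=3 min, probability 1: one expected
        # visit whose duration is within two ping gaps of the bout length
        rng = np.random.default_rng(0)
        base = pd.Timestamp("2017-06-01", tz="UTC")
        times, t = [], 0.0
        while t <= 3600:
            times.append(base + pd.Timedelta(seconds=t))
            t += rng.uniform(60, 180)
        tr = pd.DataFrame(
            {
                "transmitter_id": "A",
                "receiver_id": "SINJ",
                "bout_id": "A-1",
                "timestamp": times,
            }
        )
        out = truth_visit_table(tr, timeout_min=17.1)
        assert len(out) == 1
        assert out.loc[0, "duration_min"] == pytest.approx(60.0, abs=2 * 3.0)

    def test_outage_splits_bout_into_two_visits(self):
        base = pd.Timestamp("2017-06-01", tz="UTC")
        times = [base + pd.Timedelta(minutes=m) for m in (0, 2, 4, 40, 42, 44)]
        tr = pd.DataFrame(
            {
                "transmitter_id": "A",
                "receiver_id": "SINJ",
                "bout_id": "A-1",
                "timestamp": times,
            }
        )
        out = truth_visit_table(tr, timeout_min=17.1)
        assert len(out) == 2
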