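import numpy as np
import pandas as pd
import pytest

from rayvisits import (
    classify_visits,
    count_long_visits,
    group_share_percent,
    proportion_visit_time,
    round_half_away,
    species_proportions,
    summarize_detections,
    summarize_diel,
    summarize_visits,
)
from rayvisits import example_tables as ex
from conftest import make_detections

TAGS = pd.DataFrame(
    {"transmitter_id": ["A1", "A2", "B1"], "species": ["A_narinari", "A_narinari", "R_bonasus"]}
)


def test_round_half_away_convention():
    assert round_half_away(64.45, 1) == 64.5
    assert round_half_away(-0.05, 1) == -0.1
    assert round_half_away(11.254, 1) == 11.3


class TestSummarizeDetections:
    def _det(self):
        rows = [("2017-06-01T00:00:00Z", "A1", "R1")] * 0
        recs = []
        base = pd.Timestamp("2017-06-01", tz="UTC")
        for i in range(6):
            recs.append(((base + pd.Timedelta(minutes=i)).isoformat(), "A1", "R1"))
        for i in range(2):
            recs.append(((base + pd.Timedelta(minutes=i)).isoformat(), "A2", "R2"))
        for i in range(4):
            recs.append(((base + pd.Timedelta(minutes=i)).isoformat(), "B1", "R1"))
        return make_detections(recs)

    def test_counts_proportions_margins(self):
        out = summarize_detections(self._det(), TAGS)
        a_r1 = out.query("species=='A_narinari' and receiver_id=='R1'").iloc[0]
        assert a_r1["n_detections"] == 6
        assert a_r1["prop_of_species_total"] == pytest.approx(6 / 8)
        total = out.query("species=='A_narinari' and receiver_id=='Total'").iloc[0]
        assert total["n_detections"] == 8
        assert total["unique_tags"] == 2

    def test_single_receiver_is_hundred_percent(self):
        det = self._det()
        det["receiver_id"] = "R9"
        out = summarize_detections(det, TAGS)
        cells = out[out["receiver_id"] != "Total"]
        assert (cells["prop_of_species_total"] == 1.0).all()

    def test_orphan_transmitter_raises(self):
        det = self._det()
        det.loc[0, "transmitter_id"] = "ghost"
        with pytest.raises(ValueError):
            summarize_detections(det, TAGS)

    def test_proportions_sum_to_one(self):
        out = summarize_detections(self._det(), TAGS)
        sums = species_proportions(out).groupby(
            out.loc[out["receiver_id"] != "Total", "species"]
        ).sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestPublishedDetectionTable:
    """The bundled two-year study table reproduces its reported shares."""

    def test_eagle_ray_busiest_receiver_share(self):
        counts = ex.detection_counts()
        cells = counts.set_index(["species", "receiver_id"])
        prop = cells.loc[("A_narinari", "SINJ"), "n_detections"] / counts[
            counts["species"] == "A_narinari"
        ]["n_detections"].sum()
        assert round_half_away(100 * prop, 1) == 64.5

    def test_pooled_cownose_clam_lease_share(self):
        counts = ex.detection_counts()
        share = group_share_percent(
            counts, ex.CLAM_LEASE_RECEIVERS, ["R_bonasus", "R_brasiliensis"]
        )
        assert share == 11.3

    def test_diel_totals_consistent_with_detection_totals(self):
        diel = ex.diel_detection_totals()
        counts = ex.detection_counts()
        merged = (
            diel.groupby(["species", "receiver_id"])["total"].sum().reset_index()
        ).merge(counts, on=["species", "receiver_id"])
        pd.testing.assert_series_equal(
            merged["total"], merged["n_detections"], check_names=False
        )


class TestSummarizeDiel:
    def test_mean_over_tag_dates(self):
        base = pd.Timestamp("2017-06-01 12:00", tz="UTC")
        recs = []
        for day in range(2):
            for i in range(10):
                recs.append(
                    ((base + pd.Timedelta(days=day, minutes=i)).isoformat(), "A1", "R1")
                )
        det = make_detections(recs)
        det["diel"] = "day"
        det["date_local"] = pd.to_datetime(det["timestamp"]).dt.date
        out = summarize_diel(det, TAGS)
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(10.0)
        assert row["se"] == pytest.approx(0.0)
        assert row["total"] == 20
        assert (out["diel"] == "day").all()

    def test_day_plus_night_equals_receiver_total(self, small_sim):
        from rayvisits import annotate_detections, tags_frame

        det = annotate_detections(small_sim.detections)
        tags = tags_frame(small_sim.tags)
        diel = summarize_diel(det, tags)
        by_rec = diel.groupby(["species", "receiver_id"])["total"].sum()
        direct = (
            det.merge(tags[["transmitter_id", "species"]], on="transmitter_id")
            .groupby(["species", "receiver_id"])
            .size()
        )
        pd.testing.assert_series_equal(by_rec.sort_index(), direct.sort_index(),
                                       check_names=False)


class TestSummarizeVisits:
    def _visits(self):
        base = pd.Timestamp("2017-06-01", tz="UTC")
        return pd.DataFrame(
            {
                "transmitter_id": ["A1", "A1", "B1"],
                "receiver_id": ["R1", "R1", "R2"],
                "start": [base, base + pd.Timedelta(hours=2), base],
                "end": [base + pd.Timedelta(minutes=10),
                        base + pd.Timedelta(hours=2, minutes=20), base + pd.Timedelta(minutes=5)],
                "duration_min": [10.0, 20.0, 5.0],
                "n_detections": [5, 8, 3],
            }
        )

    def test_cell_stats_and_margins(self):
        out = summarize_visits(self._visits(), TAGS)
        cell = out.query("species=='A_narinari' and receiver_id=='R1'").iloc[0]
        assert cell["n_visits"] == 2
        assert cell["mean_min"] == pytest.approx(15.0)
        assert cell["total_time_min"] == pytest.approx(30.0)
        assert (cell["min_min"], cell["max_min"]) == (10.0, 20.0)
        margin = out.query("species=='A_narinari' and receiver_id=='Total'").iloc[0]
        assert margin["total_time_min"] == pytest.approx(30.0)

    def test_single_visit_se_zero_by_convention(self):
        out = summarize_visits(self._visits(), TAGS)
        cell = out.query("species=='R_bonasus'").iloc[0]
        assert cell["n_visits"] == 1
        assert cell["se_min"] == 0.0


class TestPublishedVisitTable:
    def test_total_visits_margin(self):
        vs = ex.visit_summary()
        assert vs["n_visits"].sum() == 17_014

    def test_eagle_total_time_margin(self):
        vs = ex.visit_summary()
        eagle = vs[vs["species"] == "A_narinari"]
        assert eagle["total_time_min"].sum() == pytest.approx(413_583.3)

    def test_eagle_inlet_visit_time_share(self):
        vs = ex.visit_summary()
        out = proportion_visit_time(vs, ex.REGION)
        eagle_inlet = out.query("species=='A_narinari' and group=='inlet'").iloc[0]
        assert eagle_inlet["percent"] == 85.3

    def test_atlantic_cownose_clam_lease_time_share(self):
        vs = ex.visit_summary()
        out = proportion_visit_time(vs, ex.GENERAL_LOCATION)
        cell = out.query("species=='R_bonasus' and group=='clam_lease'").iloc[0]
        assert cell["percent"] == 41.6

    def test_shares_sum_to_hundred(self):
        vs = ex.visit_summary()
        out = proportion_visit_time(vs, ex.REGION)
        sums = out.groupby("species")["percent"].sum()
        assert np.allclose(sums, 100.0, atol=0.1 * len(ex.RECEIVERS))

    def test_degenerate_single_group(self):
        vs = ex.visit_summary()
        out = proportion_visit_time(vs, {r: "all" for r in ex.RECEIVERS})
        assert (out["percent"] == 100.0).all()


class TestCountLongVisits:
    def test_strict_threshold_counting(self):
        v = pd.DataFrame(
            {
                "transmitter_id": ["A1"] * 4,
                "receiver_id": ["R1"] * 4,
                "duration_min": [5.0, 18.0, 17.1, 400.0],
            }
        )
        out = count_long_visits(classify_visits(v, 17.1), TAGS)
        assert out["n_long_visits"].sum() == 2

    def test_empty_visits(self):
        v = pd.DataFrame(
            {"transmitter_id": [], "receiver_id": [], "duration_min": []}
        )
        out = count_long_visits(classify_visits(v, 17.1), TAGS)
        assert out.empty

    def test_simulated_exceedance_exact(self, small_sim):
        from rayvisits import extract_visits, tags_frame
        from rayvisits.simdata import truth_visit_table

        truth = truth_visit_table(small_sim.transmissions)
        tags = tags_frame(small_sim.tags)
        out = count_long_visits(classify_visits(truth, 17.1), tags)
        assert out["n_long_visits"].sum() == (truth["duration_min"] > 17.1).sum()
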