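"""Index-date strategies and cross-sectional window cohorts."""

from __future__ import annotations

import pandas as pd
import pytest

from regforge import cohorts, missing, synth, windows
from tests.conftest import make_bundle
from tests.oracles import brute_window_cohort


def _labels(*rows):
    return pd.DataFrame(rows, columns=["episode_id", "status", "provenance"])


def _episodes(*rows):
    df = pd.DataFrame(
        rows,
        columns=["episode_id", "patient_id", "eligibility_date", "start_date", "end_date"],
    )
    for c in ("eligibility_date", "start_date", "end_date"):
        df[c] = pd.to_datetime(df[c])
    return df


class TestMeanLag:
    def test_two_point_mean(self):
        episodes = _episodes(
            ("E1", "P1", "2012-01-01", "2012-01-11", "2012-06-01"),
            ("E2", "P2", "2012-01-01", "2012-01-21", "2012-06-01"),
        )
        labels = _labels(("E1", "enrolled", "derived_A"), ("E2", "enrolled", "derived_A"))
        assert windows.mean_eligibility_to_enrollment_lag(labels, episodes) == 15.0

    def test_zero_lags(self):
        episodes = _episodes(("E1", "P1", "2012-01-01", "2012-01-01", "2012-06-01"))
        labels = _labels(("E1", "enrolled", "derived_A"))
        assert windows.mean_eligibility_to_enrollment_lag(labels, episodes) == 0.0

    def test_no_enrolled_episode_is_an_error(self):
        episodes = _episodes(("E1", "P1", "2012-01-01", "2012-01-05", "2012-06-01"))
        labels = _labels(("E1", "opt_out", "derived_A"))
        with pytest.raises(windows.UndefinedLagError):
            windows.mean_eligibility_to_enrollment_lag(labels, episodes)

    def test_planted_lags_mean(self):
        lags = [3, 7, 11, 19, 30]
        episodes = _episodes(*[
            (f"E{i}", f"P{i}", "2012-01-01",
             pd.Timestamp("2012-01-01") + pd.Timedelta(days=lag), "2012-06-01")
            for i, lag in enumerate(lags)
        ])
        labels = _labels(*[(f"E{i}", "enrolled", "derived_A") for i in range(len(lags))])
        assert windows.mean_eligibility_to_enrollment_lag(labels, episodes) == sum(lags) / 5


class TestIndexDates:
    def setup_method(self):
        self.episodes = _episodes(
            ("E1", "P1", "2011-04-01", "2012-02-15", "2012-08-01"),
            ("E2", "P1", "2013-01-01", None, "2013-06-01"),
            ("E3", "P2", "2012-01-01", "2012-01-15", "2012-07-01"),
            ("E4", "P3", "2012-01-01", None, "2012-05-01"),
        )
        self.labels = _labels(
            ("E1", "enrolled", "derived_A"),
            ("E2", "not_approached", "derived_B_unapproached"),
            ("E3", "opt_out", "derived_A"),
            ("E4", "not_approached", "derived_B_unapproached"),
        )

    def test_first_eligibility_ignores_status_and_arm(self):
        idx = windows.assign_index_dates(self.labels, self.episodes, "first_eligibility")
        dates = idx.set_index("patient_id")["index_date"]
        assert dates["P1"] == pd.Timestamp("2011-04-01")
        assert dates["P2"] == pd.Timestamp("2012-01-01")
        # one index date per patient, identical however the patient is labelled
        assert idx["patient_id"].is_unique

    def test_enrollment_linked_uses_first_enrolled_start(self):
        idx = windows.assign_index_dates(self.labels, self.episodes, "enrollment_linked")
        dates = idx.set_index("patient_id")
        assert dates.loc["P1", "index_date"] == pd.Timestamp("2012-02-15")
        assert dates.loc["P1", "arm"] == "intervention"
        # comparison patients anchor at their first eligibility by default
        assert dates.loc["P2", "index_date"] == pd.Timestamp("2012-01-01")
        assert dates.loc["P2", "arm"] == "comparison"

    def test_shifted_eligibility_adds_rounded_mean_lag(self):
        idx = windows.assign_index_dates(
            self.labels, self.episodes, "shifted_eligibility", mean_lag_days=14.0
        )
        dates = idx.set_index("patient_id")
        assert dates.loc["P3", "index_date"] == pd.Timestamp("2012-01-15")
        assert dates.loc["P1", "index_date"] == pd.Timestamp("2012-02-15")

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            windows.assign_index_dates(self.labels, self.episodes, "nope")


class TestWindowCohorts:
    def _one_patient(self, start_off, end_off, status="enrolled"):
        base = pd.Timestamp("2012-01-01")
        episodes = _episodes(
            ("E1", "P1", base, base + pd.Timedelta(days=start_off),
             base + pd.Timedelta(days=end_off)),
        )
        labels = _labels(("E1", status, "derived_A"))
        index = windows.assign_index_dates(labels, episodes, "first_eligibility")
        table = windows.build_cross_sectional_cohorts(labels, episodes, index)
        return table.at[0, "cohort"]

    def test_episode_ending_inside_window_is_completed(self):
        assert self._one_patient(0, 120) == "completed_enrollment_6m"

    def test_episode_spilling_past_window_is_incomplete(self):
        assert self._one_patient(30, 400) == "incomplete_enrollment_6m"

    def test_opt_out_only_patient_falls_through_to_opt_out(self):
        assert self._one_patient(10, 120, status="opt_out") == "opt_out_6m"

    def test_enrollment_outside_window_leaves_not_approached(self):
        assert self._one_patient(200, 300) == "not_approached_6m"

    def test_missing_index_for_labelled_patient_is_error(self):
        episodes = _episodes(("E1", "P1", "2012-01-01", "2012-01-05", "2012-03-01"))
        labels = _labels(("E1", "enrolled", "derived_A"))
        with pytest.raises(ValueError, match="index date"):
            windows.build_cross_sectional_cohorts(
                labels, episodes, pd.DataFrame(columns=["patient_id", "index_date"])
            )

    def test_agrees_with_brute_force_and_partitions(self):
        for seed in range(8):
            bundle, _ = synth.generate_registry(
                synth.GeneratorConfig(n_patients=30, n_episodes=45), seed=seed
            )
            cleaned, _, _ = missing.clean_bundle(bundle)
            labels, _ = cohorts.classify_all(cleaned)
            index = windows.assign_index_dates(labels, cleaned.episodes)
            table = windows.build_cross_sectional_cohorts(labels, cleaned.episodes, index)
            expected = brute_window_cohort(labels, cleaned.episodes, index, 183)
            got = table.set_index("patient_id")["cohort"].to_dict()
            assert got == expected
            assert len(table) == index["patient_id"].nunique()

    def test_enlarging_window_never_demotes_completed(self):
        bundle, _ = synth.generate_registry(
            synth.GeneratorConfig(n_patients=80), seed=17
        )
        cleaned, _, _ = missing.clean_bundle(bundle)
        labels, _ = cohorts.classify_all(cleaned)
        index = windows.assign_index_dates(labels, cleaned.episodes)
        small = windows.build_cross_sectional_cohorts(
            labels, cleaned.episodes, index, window_days=120
        ).set_index("patient_id")["cohort"]
        large = windows.build_cross_sectional_cohorts(
            labels, cleaned.episodes, index, window_days=240
        ).set_index("patient_id")["cohort"]
        for pid in small.index:
            if small[pid] == "completed_enrollment_6m":
                assert large[pid] == "completed_enrollment_6m"
            if large[pid] == "incomplete_enrollment_6m":
                assert small[pid] != "completed_enrollment_6m"


class TestWindowRecords:
    def test_half_open_convention_puts_index_day_in_outcome(self):
        bundle = make_bundle(
            episodes=[{"episode_id": "E1", "patient_id": "P1",
                       "eligibility_date": "2012-01-01", "start_date": "2012-01-01",
                       "end_date": "2012-06-01"}],
            contacts=[{"patient_id": "P1", "contact_date": "2012-01-01", "time_spent": 5}],
        )
        index = pd.DataFrame(
            {"patient_id": ["P1"], "index_date": [pd.Timestamp("2012-01-01")],
             "strategy": ["first_eligibility"], "arm": ["intervention"]}
        )
        slices = windows.extract_window_records(bundle, index, 90, 183)
        assert len(slices["P1"]["outcome"]["contacts"]) == 1
        assert slices["P1"]["observation"]["contacts"].empty

    def test_zero_outcome_days_gives_empty_slice(self, simple_bundle):
        index = pd.DataFrame(
            {"patient_id": ["P1"], "index_date": [pd.Timestamp("2010-01-01")],
             "strategy": ["first_eligibility"], "arm": ["intervention"]}
        )
        slices = windows.extract_window_records(simple_bundle, index, 30, 0)
        assert all(df.empty for df in slices["P1"]["outcome"].values())

    def test_slices_match_hand_enumeration(self, simple_bundle):
        index = pd.DataFrame(
            {"patient_id": ["P1"], "index_date": [pd.Timestamp("2010-02-15")],
             "strategy": ["first_eligibility"], "arm": ["intervention"]}
        )
        slices = windows.extract_window_records(simple_bundle, index, 60, 365)
        # contacts: 2010-02-01 (observation), 2010-03-01 (outcome)
        assert list(slices["P1"]["observation"]["contacts"]["contact_date"]) == [
            pd.Timestamp("2010-02-01")
        ]
        assert list(slices["P1"]["outcome"]["contacts"]["contact_date"]) == [
            pd.Timestamp("2010-03-01")
        ]
        # the episode (eligibility 2010-01-01) falls in the 60-day lookback
        assert list(slices["P1"]["observation"]["episodes"]["episode_id"]) == ["E1"]
        assert slices["P1"]["outcome"]["episodes"].empty
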