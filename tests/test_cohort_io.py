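import numpy as np
import pandas as pd
import pytest

from cogsurv import cohort_io
from cogsurv.cohort_io import (CohortValidationError, DEFAULT_ROSTER, Roster,
                               load_study_fixture, read_events, read_scores,
                               summarize_cohort, write_report)


def _score_frame(n_patients=2, timepoints=(0, 3), tests=DEFAULT_ROSTER.codes):
    rows = [{"patient_id": f"P{i}", "timepoint": t, "test_id": test,
             "score": 50.0 + i + t}
            for i in range(n_patients) for t in timepoints for test in tests]
    return pd.DataFrame(rows)


class TestScores:
    def test_well_formed_count(self, tmp_path):
        path = tmp_path / "scores.csv"
        _score_frame().to_csv(path, index=False)
        df = read_scores(path)
        assert len(df) == 2 * 2 * 10

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "scores.csv"
        path.write_text("patient_id,timepoint,test_id,score\n")
        assert len(read_scores(path)) == 0

    @pytest.mark.parametrize("mutate, match", [
        (lambda d: d.assign(timepoint=[4] + [3] * (len(d) - 1)), "row 2.*timepoint"),
        (lambda d: d.assign(test_id=["XX"] + list(d.test_id[1:])), "unknown test_id"),
        (lambda d: d.assign(score=[np.nan] + list(d.score[1:])), "non-finite"),
        (lambda d: pd.concat([d, d.iloc[[0]]]), "duplicate"),
    ])
    def test_invalid_rows_rejected(self, tmp_path, mutate, match):
        path = tmp_path / "scores.csv"
        mutate(_score_frame(1, (3,))).to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match=match):
            read_scores(path)

    def test_orientation_flip_and_roundtrip(self, tmp_path):
        roster = Roster(codes=("A", "B"), orientation={"B": -1})
        raw = pd.DataFrame({"patient_id": ["p", "p"], "timepoint": [0, 0],
                            "test_id": ["A", "B"], "score": [10.0, 30.0]})
        path = tmp_path / "s.csv"
        raw.to_csv(path, index=False)
        df = read_scores(path, roster=roster)
        # lower raw completion-time-like score = better, flipped at ingestion
        assert df.set_index("test_id")["score"].to_dict() == {"A": 10.0, "B": -30.0}
        out = tmp_path / "out.csv"
        cohort_io.write_scores(df, out, roster=roster)
        again = read_scores(out, roster=roster)
        pd.testing.assert_frame_equal(df, again)

    def test_events_roundtrip(self, tmp_path):
        ev = pd.DataFrame({
            "patient_id": ["a", "b"], "age": [61.0, 48.0],
            "event_time": [9, None], "censor_time": [None, 24],
            "censor_reason": [None, "completed_T24"]})
        path = tmp_path / "ev.csv"
        cohort_io.write_events(cohort_io.validate_events(ev), path)
        df = read_events(path)
        assert df.loc[0, "event_time"] == 9 and pd.isna(df.loc[0, "censor_time"])
        assert df.loc[1, "censor_reason"] == "completed_T24"
        out = tmp_path / "ev2.csv"
        cohort_io.write_events(df, out)
        pd.testing.assert_frame_equal(df, read_events(out))


class TestEvents:
    def test_both_times_rejected(self, tmp_path):
        path = tmp_path / "ev.csv"
        path.write_text("patient_id,age,event_time,censor_time,censor_reason\n"
                        "a,60,9,12,dropout\n")
        with pytest.raises(CohortValidationError, match="exactly one"):
            read_events(path)

    def test_neither_time_rejected(self, tmp_path):
        path = tmp_path / "ev.csv"
        path.write_text("patient_id,age,event_time,censor_time,censor_reason\n"
                        "a,60,,,\n")
        with pytest.raises(CohortValidationError, match="exactly one"):
            read_events(path)

    def test_duplicate_patient_rejected(self, tmp_path):
        path = tmp_path / "ev.csv"
        path.write_text("patient_id,age,event_time,censor_time,censor_reason\n"
                        "a,60,9,,\na,61,12,,\n")
        with pytest.raises(CohortValidationError, match="more than once"):
            read_events(path)


class TestFixture:
    def test_printed_countables(self):
        df = load_study_fixture()
        assert len(df) == 25
        assert (df["diagnosis"] == "AA").sum() == 4
        assert (df["diagnosis"] == "GBM").sum() == 21
        assert df["pd_during_followup"].sum() == 15
        assert (df["hemisphere"] == "Left").sum() == 10
        assert (df["hemisphere"] == "Right").sum() == 15

    def test_location_counts_match_sample_table(self):
        # the sample-characteristics table groups mesiotemporal under temporal
        # and prints "parieto-temporal" for the per-patient "temporo-parietal"
        df = load_study_fixture()
        loc = df["location"].value_counts()
        assert loc["Frontal"] == 6
        assert loc["Fronto-parietal"] == 1
        assert loc["Parietal"] == 3
        assert loc["Temporo-parietal"] == 2
        assert loc["Parieto-occipital"] == 4
        assert loc["Occipital"] == 6
        assert loc["Temporal"] + loc["Mesiotemporal"] == 3

    def test_end_reasons(self):
        df = load_study_fixture()
        reasons = df["end_reason"].value_counts()
        assert reasons["PD"] == 15
        assert reasons["active_at_end"] == 4
        assert reasons["dropout"] == 3
        assert reasons["completed_T24_no_PD"] == 3


class TestSummarize:
    def test_counts_and_percentages(self):
        summary = summarize_cohort(load_study_fixture())
        by = summary.set_index(["variable", "level"])
        assert by.loc[("hemisphere", "Left"), "count"] == 10
        assert by.loc[("hemisphere", "Left"), "percent"] == pytest.approx(40.0)
        assert by.loc[("location", "Occipital"), "count"] == 6
        assert by.loc[("location", "Occipital"), "percent"] == pytest.approx(24.0)

    def test_all_gbm_synthetic(self):
        rows = pd.DataFrame({"diagnosis": ["GBM"] * 4})
        summary = summarize_cohort(rows, variables=("diagnosis",))
        assert summary["count"].tolist() == [4]
        assert summary["percent"].tolist() == [100.0]

    def test_empty_cohort_rejected(self):
        with pytest.raises(CohortValidationError):
            summarize_cohort(pd.DataFrame({"diagnosis": []}))


class TestReport:
    PAYLOAD = {"n_patients": 3, "n_events": 2, "median_time_to_pd": 9,
               "median_time_to_cd": 6,
               "fit": {"hazard_ratios": {"cd_status": {"hr": 5.0, "lo": 1.5,
                                                       "hi": 17.0}},
                       "lr_chi2": 13.6, "lr_df": 2, "p_value": 0.001,
                       "c_index": 0.8}}

    def test_deterministic_json(self, tmp_path):
        j1, t1 = write_report(self.PAYLOAD, tmp_path / "a")
        j2, _ = write_report(self.PAYLOAD, tmp_path / "b")
        assert j1.read_bytes() == j2.read_bytes()
        assert "HR[cd_status]" in t1.read_text()

    def test_empty_cohort_writes_nothing(self, tmp_path):
        with pytest.raises(CohortValidationError):
            write_report({"n_patients": 0}, tmp_path / "r")
        assert not (tmp_path / "r.json").exists()
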