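"""Event-table IO, validation, model-frame layouts, and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from weibmix import (
    EventTable,
    build_model_frame,
    describe_covariates,
    describe_events,
    read_event_table,
    simple_config,
    simulate_cohort,
    write_event_table,
)
from weibmix.data import NO_EVENT, ValidationError


def _table(rec_rows, cov=None, fu=None):
    rec = pd.DataFrame(
        rec_rows, columns=["subject_id", "event_type", "occurrence_index", "time", "status"]
    )
    subjects = sorted(set(rec["subject_id"]))
    if cov is None:
        cov = pd.DataFrame({"x": np.zeros(len(subjects))},
                           index=pd.Index(subjects, name="subject_id"))
    if fu is None:
        fu = pd.Series(10.0, index=cov.index)
    return EventTable(records=rec, covariates=cov, followup_end=fu)


class TestValidation:
    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError, match="negative time"):
            _table([("a", "mi", 1, -1.0, 1)])

    def test_duplicate_occurrence_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            _table([("a", "mi", 1, 1.0, 1), ("a", "mi", 1, 2.0, 1)])

    def test_same_type_tied_times_rejected(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            _table([("a", "mi", 1, 1.0, 1), ("a", "mi", 2, 1.0, 1)])

    def test_different_type_tied_times_kept(self):
        t = _table([("a", "mi", 1, 1.0, 1), ("a", "stroke", 1, 1.0, 1)])
        assert len(t.events()) == 2

    def test_censor_row_must_terminate_stream(self):
        with pytest.raises(ValidationError, match="censoring"):
            _table([("a", "mi", 1, 1.0, 0), ("a", "mi", 2, 2.0, 1)])

    def test_event_after_followup_rejected(self):
        with pytest.raises(ValidationError, match="followup"):
            _table([("a", "mi", 1, 11.0, 1)])

    def test_subject_without_covariates_rejected(self):
        cov = pd.DataFrame({"x": [0.0]}, index=pd.Index(["b"], name="subject_id"))
        with pytest.raises(ValidationError, match="covariates"):
            EventTable(
                records=pd.DataFrame(
                    [("a", "mi", 1, 1.0, 1)],
                    columns=["subject_id", "event_type", "occurrence_index", "time", "status"],
                ),
                covariates=cov,
                followup_end=pd.Series(10.0, index=cov.index),
            )


class TestIO:
    def test_small_file_round_trip(self, tmp_path):
        path = tmp_path / "ev.csv"
        path.write_text(
            "subject_id,event_type,time,status,x\n"
            "a,mi,1.0,1,0.5\n"
            "a,mi,2.0,1,0.5\n"
            "a,stroke,1.5,1,0.5\n"
        )
        t = read_event_table(path)
        assert len(t.records) == 3
        assert t.n_subjects == 1
        assert list(t.covariates.columns) == ["x"]

    def test_negative_time_cites_row(self, tmp_path):
        path = tmp_path / "ev.csv"
        path.write_text(
            "subject_id,event_type,time,status\na,mi,1.0,1\na,mi,-1,1\n"
        )
        with pytest.raises(ValidationError, match="row"):
            read_event_table(path)

    def test_missing_mapped_column(self, tmp_path):
        path = tmp_path / "ev.csv"
        path.write_text("subject_id,kind,time,status\na,mi,1.0,1\n")
        with pytest.raises(ValidationError, match="missing mapped column"):
            read_event_table(path)
        # a schema naming the column fixes it
        t = read_event_table(path, schema={"event_type": "kind"})
        assert t.events().loc[0, "event_type"] == "mi"

    def test_simulated_cohort_round_trips(self, tmp_path):
        cfg = simple_config("m4", n_subjects=100, seed=5)
        table = simulate_cohort(cfg)
        path = tmp_path / "cohort.csv"
        write_event_table(table, path)
        back = read_event_table(path)
        assert back.n_subjects == table.n_subjects
        pd.testing.assert_frame_equal(
            back.events().reset_index(drop=True),
            table.events().reset_index(drop=True),
            check_dtype=False,
            check_like=True,
        )
        assert np.allclose(
            back.followup_end.sort_index(), table.followup_end.sort_index()
        )
        got = back.covariates.sort_index()[table.covariates.columns]
        assert np.allclose(got.to_numpy(float), table.covariates.sort_index().to_numpy(float))

    def test_day_to_year_conversion(self, tmp_path):
        path = tmp_path / "ev.csv"
        path.write_text("subject_id,event_type,time,status\na,mi,365.25,1\n")
        t = read_event_table(path, time_divisor=365.25)
        assert t.events().loc[0, "time"] == pytest.approx(1.0)


class TestModelFrames:
    def test_m3_counts_one_per_type(self, stroke_angina_table):
        """Two strokes then an angina count as two type-streams: the first
        stroke (day 10) and the angina (day 150)."""
        fr = build_model_frame(stroke_angina_table, "m3")
        a = fr.data[fr.data["subject_id"] == "a"]
        ev = a[a["status"] == 1].set_index("event_type")
        assert len(ev) == 2
        assert ev.loc["stroke", "time"] == pytest.approx(10 / 365)
        assert ev.loc["angina", "time"] == pytest.approx(150 / 365)
        # censoring rows at followup for the event-free subject
        b = fr.data[fr.data["subject_id"] == "b"]
        assert (b["status"] == 0).all() and len(b) == 2

    def test_m1_keeps_earliest_event(self, stroke_angina_table):
        fr = build_model_frame(stroke_angina_table, "m1")
        a = fr.data[fr.data["subject_id"] == "a"].iloc[0]
        assert a["time"] == pytest.approx(10 / 365)
        assert a["status"] == 1
        assert fr.n_rows == 2  # exactly one row per subject

    def test_m2_m4_row_counts_by_enumeration(self, stroke_angina_table):
        K = 2
        m2 = build_model_frame(stroke_angina_table, "m2")
        # 3 event rows + 1 terminal censoring row per subject
        assert m2.n_rows == 3 + 2
        m4 = build_model_frame(stroke_angina_table, "m4")
        # 3 event rows + K censoring rows per subject
        assert m4.n_rows == 3 + 2 * K
        m3 = build_model_frame(stroke_angina_table, "m3")
        assert m3.n_rows == 2 * K

    def test_entry_times_track_previous_event(self, stroke_angina_table):
        m4 = build_model_frame(stroke_angina_table, "m4")
        stroke = m4.data[
            (m4.data["subject_id"] == "a") & (m4.data["event_type"] == "stroke")
        ].sort_values("time")
        assert list(stroke["entry"]) == pytest.approx([0.0, 10 / 365, 100 / 365])

    def test_gap_timescale_resets_clock(self, stroke_angina_table):
        m4 = build_model_frame(stroke_angina_table, "m4", timescale="gap")
        assert (m4.data["entry"] == 0).all()
        stroke = m4.data[
            (m4.data["subject_id"] == "a")
            & (m4.data["event_type"] == "stroke")
            & (m4.data["status"] == 1)
        ]
        assert sorted(stroke["time"]) == pytest.approx([10 / 365, 90 / 365])

    def test_missing_covariates_dropped(self, stroke_angina_table):
        t = stroke_angina_table
        t.covariates.loc["b", "x"] = np.nan
        fr = build_model_frame(t, "m1")
        assert fr.n_subjects == 1

    def test_unknown_covariate_errors(self, stroke_angina_table):
        with pytest.raises(KeyError):
            build_model_frame(stroke_angina_table, "m1", covariates=["nope"])


class TestDescribe:
    def test_single_subject_no_events(self):
        cov = pd.DataFrame({"x": [0.0]}, index=pd.Index(["a"], name="subject_id"))
        t = EventTable(
            records=pd.DataFrame(
                {"subject_id": pd.Series(dtype=object),
                 "event_type": pd.Series(dtype=object),
                 "occurrence_index": pd.Series(dtype=int),
                 "time": pd.Series(dtype=float),
                 "status": pd.Series(dtype=int)}
            ),
            covariates=cov,
            followup_end=pd.Series(10.0, index=cov.index),
        )
        summ = describe_events(t)
        assert summ.loc[summ["event_type"] == "no event", "percent"].iloc[0] == 100.0

    def test_percentages_sum_to_100_vs_independent_tally(self, m4_cohort):
        summ = describe_events(m4_cohort)
        # independent recount with a plain groupby
        ev = m4_cohort.records[m4_cohort.records["status"] == 1]
        tally = ev.groupby("event_type").size()
        for _, row in summ[summ["event_type"] != "no event"].iterrows():
            assert row["count"] == tally[row["event_type"]]
        assert summ["percent"].sum() == pytest.approx(100.0, abs=0.15)
        assert summ["count"].sum() == summ.attrs["grand_total"]

    def test_indicator_and_continuous_summaries(self):
        cov = pd.DataFrame(
            {"male": [1, 0, 1, 0, np.nan], "age": [70.0, 72.0, 74.0, 71.0, 73.0],
             "const": [1, 1, 1, 1, 1]},
            index=pd.Index(list("abcde"), name="subject_id"),
        )
        t = EventTable(
            records=pd.DataFrame(
                {"subject_id": pd.Series(dtype=object),
                 "event_type": pd.Series(dtype=object),
                 "occurrence_index": pd.Series(dtype=int),
                 "time": pd.Series(dtype=float),
                 "status": pd.Series(dtype=int)}
            ),
            covariates=cov,
            followup_end=pd.Series(10.0, index=cov.index),
        )
        summ = describe_covariates(t).set_index("covariate")
        assert summ.loc["male", "n"] == 4  # missing excluded from denominator
        assert summ.loc["male", "percent"] == 50.0
        assert summ.loc["age", "mean"] == pytest.approx(72.0)
        assert summ.loc["const", "kind"] == "indicator"
        # constant continuous column: sd must be 0
        cov2 = cov.assign(flat=2.5)
        t2 = EventTable(records=t.records, covariates=cov2, followup_end=t.followup_end)
        s2 = describe_covariates(t2).set_index("covariate")
        assert s2.loc["flat", "sd"] == pytest.approx(0.0)
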