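import datetime as dt

import pytest

from stepcoach import (
    CleaningRule,
    DailyRecord,
    StudyPeriod,
    adherence_percentage,
    clean_step_series,
    load_cohort_records,
    load_daily_records,
    reminder_due,
    save_cohort_records,
    summarize_period,
    window_period,
)
from stepcoach.errors import ParseError, UndefinedValueError, ValidationError

D0 = dt.date(2024, 1, 1)


def _csv(tmp_path, text, name="records.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "participant_id,date,steps,worn,recording_failure,sbp_m,dbp_m,sbp_n,dbp_n,weight_kg,glucose_mgdl,kcal_activity\n"


class TestLoading:
    def test_well_formed_rows_parse_one_record_each(self, tmp_path):
        path = _csv(
            tmp_path,
            HEADER
            + "p1,2024-01-01,10000,true,,130,85,125,80,66.2,,310\n"
            + "p1,2024-01-02,9000,true,,,,,,,,\n"
            + "p1,2024-01-03,,false,,131,86,,,,,\n",
        )
        recs = load_daily_records(path)
        assert len(recs) == 3
        assert recs[0].steps == 10000 and recs[0].sbp_m == 130
        assert recs[1].sbp_m is None  # empty cell -> missing, never zero
        assert recs[2].steps is None and recs[2].worn is False  # record retained

    def test_duplicate_date_rejected_with_line_number(self, tmp_path):
        path = _csv(
            tmp_path,
            HEADER + "p1,2024-01-01,100,,,,,,,,,\n" + "p1,2024-01-01,200,,,,,,,,,\n",
        )
        with pytest.raises(ValidationError, match="line 3"):
            load_daily_records(path)

    def test_malformed_cell_names_the_line(self, tmp_path):
        path = _csv(tmp_path, HEADER + "p1,2024-01-01,ten,,,,,,,,,\n")
        with pytest.raises(ParseError, match="line 2"):
            load_daily_records(path)

    def test_multi_participant_file_needs_explicit_id(self, tmp_path):
        path = _csv(
            tmp_path,
            HEADER + "p1,2024-01-01,100,,,,,,,,,\n" + "p2,2024-01-01,200,,,,,,,,,\n",
        )
        with pytest.raises(ValidationError):
            load_daily_records(path)
        assert load_daily_records(path, "p2")[0].steps == 200

    def test_round_trip_preserves_values(self, tmp_path):
        cohort = {
            "p1": [
                DailyRecord(D0, steps=10000, worn=True, sbp_m=131.5, weight_kg=66.2),
                DailyRecord(D0 + dt.timedelta(days=1)),
            ]
        }
        path = tmp_path / "out.csv"
        save_cohort_records(cohort, path)
        back = load_cohort_records(path)
        assert back["p1"][0].sbp_m == 131.5
        assert back["p1"][1].steps is None


class TestValidation:
    def test_negative_steps_rejected(self):
        with pytest.raises(ValidationError):
            DailyRecord(D0, steps=-1)

    def test_bp_outside_validity_range_rejected(self):
        with pytest.raises(ValidationError):
            DailyRecord(D0, sbp_m=450.0)

    def test_implausible_bp_inside_range_warns_but_is_kept(self):
        with pytest.warns(UserWarning, match="implausible"):
            rec = DailyRecord(D0, sbp_m=25.0)
        assert rec.sbp_m == 25.0


class TestCleaning:
    def test_low_count_and_nonwear_days_excluded(self, make_records):
        recs = make_records([(50, True), (100, True), (5000, False), (8000, True), None])
        kept = clean_step_series(recs)
        # 50 steps falls under the <100 exclusion; exactly 100 is retained
        assert [r.steps for r in kept] == [100, 8000]

    def test_missing_worn_flag_treated_as_worn(self, make_records):
        rec = DailyRecord(D0, steps=5000, worn=None)
        assert clean_step_series([rec]) == [rec]

    def test_idempotent_and_subset(self, make_records):
        recs = make_records([(50, True), (200, True), (5000, False), (9000, True)])
        once = clean_step_series(recs)
        assert clean_step_series(once) == once
        assert set(r.date for r in once) <= set(r.date for r in recs)

    def test_custom_threshold(self, make_records):
        recs = make_records([(150, True), (250, True)])
        assert [r.steps for r in clean_step_series(recs, CleaningRule(min_valid_steps=200))] == [250]


class TestWindows:
    def test_baseline_window_is_14_days(self, make_records):
        recs = make_records([(1000 + i, True) for i in range(200)])
        assert len(window_period(recs, StudyPeriod.baseline())) == 14

    def test_p1b_covers_weeks_5_to_6(self):
        p1b = StudyPeriod.p1b()
        assert (p1b.start_day, p1b.end_day) == (14 + 5 + 29, 14 + 5 + 42)
        assert p1b.n_days == 14

    def test_p2b_covers_weeks_23_to_24(self):
        p2b = StudyPeriod.p2b()
        assert p2b.n_days == 14 and p2b.end_day == 14 + 5 + 7 * 24

    def test_single_week_window_has_7_days(self, make_records):
        recs = make_records([(1000, True)] * 200)
        week5 = StudyPeriod.intervention_weeks(5, 5)
        assert len(window_period(recs, week5)) == 7

    def test_empty_series_gives_empty_window(self):
        assert window_period([], StudyPeriod.baseline()) == []

    def test_inverted_period_rejected(self):
        with pytest.raises(ValidationError):
            StudyPeriod("bad", 10, 5)


class TestAdherence:
    def test_recording_failure_days_leave_the_denominator(self, make_records):
        recs = make_records([(1000, True)] * 13)
        recs.append(DailyRecord(D0 + dt.timedelta(days=13), recording_failure=True))
        assert adherence_percentage(recs, StudyPeriod.baseline(), "steps") == 100.0

    def test_half_recorded_gives_50_percent(self, make_records):
        recs = make_records([(1000, True)] * 7 + [None] * 7)
        assert adherence_percentage(recs, StudyPeriod.baseline(), "steps") == 50.0

    def test_all_failure_days_is_undefined(self):
        recs = [
            DailyRecord(D0 + dt.timedelta(days=i), recording_failure=True) for i in range(14)
        ]
        with pytest.raises(UndefinedValueError):
            adherence_percentage(recs, StudyPeriod.baseline(), "steps")

    def test_monotone_in_recorded_days(self, make_records):
        values = []
        for k in range(0, 15):
            recs = make_records([(1000, True)] * k + [None] * (14 - k))
            values.append(adherence_percentage(recs, StudyPeriod.baseline(), "steps"))
        assert values == sorted(values)
        assert all(0 <= v <= 100 for v in values)


class TestReminder:
    def test_three_missing_days_triggers(self, make_records):
        recs = make_records([(1000, True)] * 5 + [None, None, None])
        assert reminder_due(recs, D0 + dt.timedelta(days=8)) is True

    def test_recent_recording_suppresses(self, make_records):
        recs = make_records([(1000, True)] * 5 + [None, None, (800, True)])
        assert reminder_due(recs, D0 + dt.timedelta(days=8)) is False

    def test_short_history_never_triggers(self, make_records):
        recs = make_records([None, None])
        assert reminder_due(recs, D0 + dt.timedelta(days=2)) is False


class TestSummaries:
    def test_mean_over_valid_days_only(self, make_records):
        recs = make_records([(10000, True), (12000, True), (50, True), (9000, False)] + [None] * 10)
        s = summarize_period(recs, StudyPeriod.baseline())
        assert s.mean_steps == 11000
        assert s.n_days["steps"] == 2

    def test_bp_mean_uses_available_days(self):
        recs = [
            DailyRecord(D0 + dt.timedelta(days=i), sbp_m=130.0 + i) for i in range(5)
        ] + [DailyRecord(D0 + dt.timedelta(days=i)) for i in range(5, 14)]
        s = summarize_period(recs, StudyPeriod.baseline())
        assert s.sbp_morning == 132.0 and s.n_days["sbp_m"] == 5

    def test_all_missing_parameter_is_absent_not_zero(self, make_records):
        s = summarize_period(make_records([(10000, True)] * 14), StudyPeriod.baseline())
        assert s.weight is None and s.n_days["weight_kg"] == 0

    def test_constant_series_mean_is_the_constant(self, make_records):
        s = summarize_period(make_records([(7500, True)] * 14), StudyPeriod.baseline())
        assert s.mean_steps == 7500
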