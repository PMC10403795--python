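"""Daily device records: data model, CSV I/O, cleaning, windowing, adherence.

A participant carries a triaxial accelerometer during waking hours and
measures home blood pressure twice a day (morning before breakfast, night
before bedtime) plus daily body weight.  One :class:`DailyRecord` holds one
calendar day of those measurements.  Step analyses exclude self-reported
non-wear days and days with fewer than 100 recorded steps; the cleaning rule
lives in :class:`CleaningRule` so it can be tightened or relaxed explicitly.

Study-day indexing: study day 1 is the first day of the 2-week baseline
device period (P0b).  The intervention starts after a short non-study gap
(5 days by default); intervention week *w* is the consecutive 7-day block
starting at intervention day ``1 + 7*(w-1)``.  The step-outcome windows are
P1b (intervention weeks 5-6) and P2b (weeks 23-24).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, UndefinedValueError, ValidationError

__all__ = [
    "DailyRecord",
    "StudyPeriod",
    "Participant",
    "MedicationEvent",
    "CleaningRule",
    "PeriodSummary",
    "BASELINE_DAYS",
    "GAP_DAYS",
    "PARAMETERS",
    "STAGES",
    "load_daily_records",
    "load_cohort_records",
    "save_cohort_records",
    "clean_step_series",
    "window_period",
    "adherence_percentage",
    "reminder_due",
    "summarize_period",
]

#: Days in the baseline device period (P0b).
BASELINE_DAYS = 14
#: Non-study days between the end of P0b and intervention day 1.
GAP_DAYS = 5

#: Parameters that can be measured on a given day (CSV column names).
PARAMETERS = (
    "steps",
    "sbp_m",
    "dbp_m",
    "sbp_n",
    "dbp_n",
    "weight_kg",
    "glucose_mgdl",
    "kcal_activity",
)

#: Transtheoretical-model stages of change.
STAGES = (
    "precontemplation",
    "contemplation",
    "preparation",
    "action",
    "maintenance",
)

_BP_FIELDS = ("sbp_m", "dbp_m", "sbp_n", "dbp_n")


@dataclass(frozen=True)
class DailyRecord:
    """One calendar day of device measurements for one participant.

    Missing measurements are ``None``, never zero.  ``worn`` is the
    self-reported wear flag (``None`` = not reported, treated as worn for
    cleaning purposes); ``recording_failure`` marks days lost to device or
    system failure not attributable to the participant.
    """

    date: dt.date
    steps: int | None = None
    worn: bool | None = None
    recording_failure: bool = False
    sbp_m: float | None = None
    dbp_m: float | None = None
    sbp_n: float | None = None
    dbp_n: float | None = None
    weight_kg: float | None = None
    glucose_mgdl: float | None = None
    kcal_activity: float | None = None

    def __post_init__(self) -> None:
        if self.steps is not None and self.steps < 0:
            raise ValidationError(f"{self.date}: steps must be non-negative, got {self.steps}")
        for name in _BP_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0 < v < 400):
                raise ValidationError(f"{self.date}: {name}={v} outside (0, 400) mm Hg")
            if v is not None and not (30 <= v <= 260):
                warnings.warn(
                    f"{self.date}: implausible {name}={v} mm Hg (kept; no automatic exclusion)",
                    stacklevel=2,
                )

    def value(self, parameter: str):
        if parameter not in PARAMETERS:
            raise ValidationError(f"unknown parameter {parameter!r}")
        return getattr(self, parameter)


@dataclass(frozen=True)
class StudyPeriod:
    """A labelled inclusive range of study-day indices (day 1 = first P0b day)."""

    label: str
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValidationError(f"{self.label}: start_day {self.start_day} > end_day {self.end_day}")
        if self.start_day < 1:
            raise ValidationError(f"{self.label}: start_day must be >= 1")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1

    @classmethod
    def baseline(cls, baseline_days: int = BASELINE_DAYS) -> "StudyPeriod":
        """P0b: the baseline device period."""
        return cls("P0b", 1, baseline_days)

    @classmethod
    def intervention_weeks(
        cls,
        first_week: int,
        last_week: int,
        label: str | None = None,
        baseline_days: int = BASELINE_DAYS,
        gap_days: int = GAP_DAYS,
    ) -> "StudyPeriod":
        """Inclusive block of intervention weeks (week 1 starts after the gap)."""
        if first_week < 1 or last_week < first_week:
            raise ValidationError("weeks must satisfy 1 <= first <= last")
        day0 = baseline_days + gap_days
        return cls(
            label or f"weeks {first_week}-{last_week}",
            day0 + 1 + 7 * (first_week - 1),
            day0 + 7 * last_week,
        )

    @classmethod
    def p1b(cls, **kw) -> "StudyPeriod":
        """Intervention weeks 5-6 (short-term step-outcome window)."""
        return cls.intervention_weeks(5, 6, label="P1b", **kw)

    @classmethod
    def p2b(cls, **kw) -> "StudyPeriod":
        """Intervention weeks 23-24 (long-term step-outcome window)."""
        return cls.intervention_weeks(23, 24, label="P2b", **kw)


@dataclass(frozen=True)
class MedicationEvent:
    date: dt.date
    drug_class: str  # "hypertension" | "dyslipidemia" | other
    change: str  # "start" | "increase" | "decrease"

    def __post_init__(self) -> None:
        if self.change not in ("start", "increase", "decrease"):
            raise ValidationError(f"unknown medication change {self.change!r}")


@dataclass(frozen=True)
class Participant:
    id: str
    sex: str = "unknown"
    age: float | None = None
    stage_of_change: str | None = None
    medication_events: tuple[MedicationEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.stage_of_change is not None and self.stage_of_change not in STAGES:
            raise ValidationError(
                f"participant {self.id}: stage_of_change {self.stage_of_change!r} not one of {STAGES}"
            )


@dataclass(frozen=True)
class CleaningRule:
    """Step-series validity rule: drop self-reported non-wear days and days
    with fewer than ``min_valid_steps`` steps (default 100, strictly-less-than)."""

    min_valid_steps: int = 100
    require_worn: bool = True

    def __post_init__(self) -> None:
        if self.min_valid_steps <= 0:
            raise ValidationError("min_valid_steps must be > 0")

    def keeps(self, rec: DailyRecord) -> bool:
        if rec.steps is None:
            return False
        if self.require_worn and rec.worn is False:
            return False
        return rec.steps >= self.min_valid_steps


@dataclass(frozen=True)
class PeriodSummary:
    """Arithmetic means over valid days in a window, with n valid days per
    parameter.  A parameter with no valid days is ``None`` (never zero)."""

    period: str
    mean_steps: float | None = None
    mean_kcal: float | None = None
    sbp_morning: float | None = None
    dbp_morning: float | None = None
    sbp_night: float | None = None
    dbp_night: float | None = None
    weight: float | None = None
    glucose: float | None = None
    n_days: Mapping[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("participant_id", "date") + PARAMETERS[:1] + ("worn", "recording_failure") + PARAMETERS[1:]


def _parse_bool(cell: str, line: int, column: str) -> bool | None:
    s = cell.strip().lower()
    if s == "":
        return None
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ParseError(f"line {line}: cannot parse {column}={cell!r} as boolean")


def _parse_num(cell: str, line: int, column: str, as_int: bool = False):
    s = cell.strip()
    if s == "":
        return None
    try:
        x = float(s)
        return int(round(x)) if as_int else x
    except ValueError:
        raise ParseError(f"line {line}: cannot parse {column}={cell!r} as a number") from None


def load_cohort_records(path) -> dict[str, list[DailyRecord]]:
    """Read a daily-records CSV into per-participant, date-sorted record lists.

    Schema: ``participant_id,date,steps,worn,recording_failure,sbp_m,dbp_m,
    sbp_n,dbp_n,weight_kg,glucose_mgdl,kcal_activity`` with ISO-8601 dates and
    empty cells for missing values.  Unknown columns are preserved on disk but
    ignored here.  A duplicate (participant, date) pair is a validation error;
    a malformed cell is a parse error naming the line.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"participant_id", "date"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    out: dict[str, list[DailyRecord]] = {}
    seen: set[tuple[str, dt.date]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        row = row._asdict()
        pid = row["participant_id"].strip()
        if not pid:
            raise ParseError(f"line {line}: empty participant_id")
        try:
            date = dt.date.fromisoformat(row["date"].strip())
        except ValueError:
            raise ParseError(f"line {line}: cannot parse date={row['date']!r} (expect ISO-8601)") from None
        if (pid, date) in seen:
            raise ValidationError(f"line {line}: duplicate record for participant {pid} on {date}")
        seen.add((pid, date))
        kwargs = {
            "steps": _parse_num(row.get("steps", ""), line, "steps", as_int=True),
            "worn": _parse_bool(row.get("worn", ""), line, "worn"),
            "recording_failure": _parse_bool(row.get("recording_failure", ""), line, "recording_failure")
            or False,
        }
        for col in PARAMETERS[1:]:
            kwargs[col] = _parse_num(row.get(col, ""), line, col)
        try:
            rec = DailyRecord(date=date, **kwargs)
        except ValidationError as e:
            raise ValidationError(f"line {line}: {e}") from None
        out.setdefault(pid, []).append(rec)
    for pid in out:
        out[pid].sort(key=lambda r: r.date)
    return out


def load_daily_records(path, participant_id: str | None = None) -> list[DailyRecord]:
    """Read one participant's records from a daily-records CSV.

    With a single participant in the file the id may be omitted; otherwise
    ``participant_id`` selects whose series to return.
    """
    cohort = load_cohort_records(path)
    if participant_id is not None:
        if participant_id not in cohort:
            raise ValidationError(f"participant {participant_id!r} not present in {path}")
        return cohort[participant_id]
    if len(cohort) != 1:
        raise ValidationError(
            f"{path} contains {len(cohort)} participants; pass participant_id to choose one"
        )
    return next(iter(cohort.values()))


def save_cohort_records(cohort: Mapping[str, Sequence[DailyRecord]], path) -> None:
    """Write per-participant record lists in the documented CSV schema."""

    def cell(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, float):
            return format(v, ".6g")
        return str(v)

    rows = []
    for pid in sorted(cohort):
        for rec in cohort[pid]:
            rows.append(
                {
                    "participant_id": pid,
                    "date": rec.date.isoformat(),
                    "steps": cell(rec.steps),
                    "worn": cell(rec.worn),
                    "recording_failure": cell(rec.recording_failure) if rec.recording_failure else "",
                    **{col: cell(getattr(rec, col)) for col in PARAMETERS[1:]},
                }
            )
    pd.DataFrame(rows, columns=list(_CSV_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cleaning, windowing, adherence
# ---------------------------------------------------------------------------


def clean_step_series(
    records: Sequence[DailyRecord], rule: CleaningRule = CleaningRule()
) -> list[DailyRecord]:
    """Return only the days valid for step analysis (input unmodified).

    A day is kept iff steps are present, the wear flag is not explicitly
    ``False``, and steps >= ``rule.min_valid_steps`` (a day with exactly 100
    steps is retained under the default strictly-less-than-100 exclusion).
    Idempotent by construction.
    """
    return [r for r in records if rule.keeps(r)]


def _study_day(date: dt.date, study_start: dt.date) -> int:
    return (date - study_start).days + 1


def window_period(
    records: Sequence[DailyRecord],
    period: StudyPeriod,
    study_start: dt.date | None = None,
) -> list[DailyRecord]:
    """Subsequence of records whose study-day index falls inside ``period``.

    ``study_start`` defaults to the date of the earliest record (study day 1).
    """
    if not records:
        return []
    start = study_start or min(r.date for r in records)
    return [r for r in records if period.start_day <= _study_day(r.date, start) <= period.end_day]


def adherence_percentage(
    records: Sequence[DailyRecord],
    period: StudyPeriod,
    parameter: str,
    study_start: dt.date | None = None,
) -> float:
    """Percentage of period days on which ``parameter`` was measured and recorded.

    Days flagged ``recording_failure`` (device/system failure, not the
    participant's responsibility) are removed from the denominator.  Days with
    no record row at all count as unrecorded period days.
    """
    if parameter not in PARAMETERS:
        raise ValidationError(f"unknown parameter {parameter!r}")
    in_window = window_period(records, period, study_start)
    failures = sum(1 for r in in_window if r.recording_failure)
    denominator = period.n_days - failures
    if denominator <= 0:
        raise UndefinedValueError(
            f"{period.label}: no accountable days (all {period.n_days} flagged recording_failure)"
        )
    recorded = sum(
        1 for r in in_window if not r.recording_failure and r.value(parameter) is not None
    )
    return 100.0 * recorded / denominator


def reminder_due(records: Sequence[DailyRecord], today: dt.date) -> bool:
    """True iff the 3 most recent days (ending yesterday) all lack step data.

    Mirrors the monitoring rule that triggers an email reminder after 3
    consecutive days without accelerometer recordings.  With fewer than 3 days
    of history no reminder is due.
    """
    if not records:
        return False
    earliest = min(r.date for r in records)
    if (today - earliest).days < 3:
        return False
    by_date = {r.date: r for r in records}
    for back in (1, 2, 3):
        rec = by_date.get(today - dt.timedelta(days=back))
        if rec is not None and rec.steps is not None:
            return False
    return True


def summarize_period(
    records: Sequence[DailyRecord],
    period: StudyPeriod,
    rule: CleaningRule = CleaningRule(),
    study_start: dt.date | None = None,
) -> PeriodSummary:
    """Per-parameter arithmetic means over valid days in a window.

    Steps (and activity calories, which come from the same device) are
    averaged over cleaned step days only; the remaining parameters are
    averaged over the days they are present.  A parameter with no valid days
    is reported as ``None`` with n = 0.
    """
    in_window = window_period(records, period, study_start)
    cleaned = clean_step_series(in_window, rule)

    def mean_of(values: Iterable[float]) -> tuple[float | None, int]:
        vals = [v for v in values if v is not None]
        if not vals:
            return None, 0
        return sum(vals) / len(vals), len(vals)

    mean_steps, n_steps = mean_of(r.steps for r in cleaned)
    mean_kcal, n_kcal = mean_of(r.kcal_activity for r in cleaned)
    sbp_m, n_sbp_m = mean_of(r.sbp_m for r in in_window)
    dbp_m, n_dbp_m = mean_of(r.dbp_m for r in in_window)
    sbp_n, n_sbp_n = mean_of(r.sbp_n for r in in_window)
    dbp_n, n_dbp_n = mean_of(r.dbp_n for r in in_window)
    weight, n_weight = mean_of(r.weight_kg for r in in_window)
    glucose, n_glucose = mean_of(r.glucose_mgdl for r in in_window)
    return PeriodSummary(
        period=period.label,
        mean_steps=mean_steps,
        mean_kcal=mean_kcal,
        sbp_morning=sbp_m,
        dbp_morning=dbp_m,
        sbp_night=sbp_n,
        dbp_night=dbp_n,
        weight=weight,
        glucose=glucose,
        n_days={
            "steps": n_steps,
            "kcal_activity": n_kcal,
            "sbp_m": n_sbp_m,
            "dbp_m": n_dbp_m,
            "sbp_n": n_sbp_n,
            "dbp_n": n_dbp_n,
            "weight_kg": n_weight,
            "glucose_mgdl": n_glucose,
        },
    )
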