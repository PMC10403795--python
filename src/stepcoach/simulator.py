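"""Synthetic participants and goal-responsive step trajectories.

The simulator closes the loop around the coaching engine so the whole
intervention-plus-evaluation pipeline can run with no external data.  Each
synthetic user carries latent behavioral parameters grounded in Social
Cognitive Theory: a log-normal habitual step level, a self-efficacy score in
[0, 100], and a responsiveness that converts motivational drive into extra
steps.  An active weekly goal raises daily steps by

    effort = responsiveness * drive(self_efficacy, difficulty)

where difficulty is the goal's elevation above the user's baseline mean in
goal-increment units and drive is a logistic function of (self-efficacy -
difficulty): confident users push harder, overambitious goals sap effort.
Mastery feedback closes the loop: self-efficacy rises after a goal-met week
(mastery experience) and falls after a missed week, so a ladder that climbs
past the user's ability produces the attenuation seen in long step-count
interventions.

Study timeline: a 2-week baseline device period (P0b), a 5-day non-study
gap, then 24 intervention weeks with a weekly goal session.  Population
defaults emulate a workplace cohort of active middle-aged adults with a
baseline median near 10,000 steps/day.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .goals import (
    GoalConfig,
    GoalState,
    WeekPerformance,
    finalize_goal,
    negotiate_goal,
    suggest_next_goal,
    suggest_week1_goal,
)
from .evaluation import GOAL_LEVELS, PASR_FACTORS, QuestionnaireResponse
from .feedback import SMBPA_FACTORS
from .records import (
    BASELINE_DAYS,
    GAP_DAYS,
    CleaningRule,
    DailyRecord,
    MedicationEvent,
    Participant,
    StudyPeriod,
    clean_step_series,
    load_cohort_records,
    save_cohort_records,
    window_period,
)

__all__ = [
    "SimUser",
    "PopulationConfig",
    "SimConfig",
    "UserTrajectory",
    "TrialDataset",
    "generate_cohort",
    "simulate_user_weeks",
    "run_trial",
    "load_sim_config",
]

_DEFAULT_START = dt.date(2024, 1, 1)
_TIMEPOINTS = ("P0a", "P1a", "P2a")


@dataclass(frozen=True)
class SimUser:
    """Latent parameters of one synthetic participant."""

    id: str
    baseline_log_mean: float  # mean of daily log-steps
    baseline_log_sd: float  # within-person SD of daily log-steps
    self_efficacy: float  # latent, 0-100; seeds reported confidence
    responsiveness: float  # steps/day of extra effort at full drive
    mastery_gain: float = 2.0  # self-efficacy gain per goal-met week
    failure_loss: float = 3.0  # self-efficacy loss per missed week
    wear_prob: float = 0.97  # daily probability of a valid wear day
    dropout_hazard: float = 0.0015  # per-week probability of leaving the study
    sbp_base: float = 132.0  # morning systolic resting level, mm Hg
    dbp_base: float = 88.0
    weight_base: float = 66.0  # kg

    def __post_init__(self) -> None:
        if not (0 <= self.self_efficacy <= 100):
            raise ValidationError("self_efficacy must be in [0, 100]")
        for name in ("wear_prob", "dropout_hazard"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be a probability, got {v}")
        if self.baseline_log_sd < 0 or self.responsiveness < 0:
            raise ValidationError("baseline_log_sd and responsiveness must be >= 0")


@dataclass(frozen=True)
class PopulationConfig:
    """Distributions the cohort is drawn from.

    ``baseline_median_steps`` with ``between_sd_log`` reproduces a
    right-skewed cohort whose median P0b mean sits near the target; the
    defaults aim at the ~10,000 steps/day workplace population the engine
    targets.  Self-efficacy defaults give baseline goal-related confidence
    scores in the low 70s.
    """

    baseline_median_steps: float = 10_000.0
    between_sd_log: float = 0.22  # between-person SD of log baseline level
    within_sd_log: float = 0.25  # day-to-day SD of log steps
    self_efficacy_mean: float = 70.0
    self_efficacy_sd: float = 12.0
    responsiveness_mean: float = 2_000.0  # steps/day at full drive
    responsiveness_sd: float = 500.0
    mastery_gain: float = 2.0
    failure_loss: float = 3.0
    wear_prob: float = 0.97
    dropout_hazard: float = 0.0015
    sbp_mean: float = 132.0
    sbp_sd: float = 8.0
    dbp_mean: float = 88.0
    dbp_sd: float = 6.0
    weight_mean: float = 66.0
    weight_sd: float = 10.0
    new_bp_med_prob: float = 0.05  # chance of starting an antihypertensive mid-study
    #: Table-style stage-of-change mix of the main analysis population.
    stage_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "contemplation": 0.17,
            "preparation": 0.56,
            "action": 0.10,
            "maintenance": 0.17,
        }
    )

    def __post_init__(self) -> None:
        if self.baseline_median_steps <= 0:
            raise ValidationError("baseline_median_steps must be positive")
        if abs(sum(self.stage_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("stage_probs must sum to 1")


@dataclass(frozen=True)
class SimConfig:
    """Everything that defines a virtual trial besides the seed."""

    population: PopulationConfig = PopulationConfig()
    goal: GoalConfig = GoalConfig()
    weeks: int = 24
    baseline_days: int = BASELINE_DAYS
    gap_days: int = GAP_DAYS
    study_start: dt.date = _DEFAULT_START
    # drive(se, difficulty) = expit((se - midpoint - difficulty_weight*difficulty)/scale)
    drive_midpoint: float = 50.0
    drive_difficulty_weight: float = 5.0
    drive_scale: float = 15.0
    # reported confidence = clamp(se - conf_difficulty_weight*difficulty + noise)
    conf_difficulty_weight: float = 4.0
    conf_noise_sd: float = 5.0
    nonwear_step_fraction: float = 0.3  # fraction of true steps counted on non-wear days
    bp_record_prob: float = 0.95
    bp_slope_per_1000: float = 0.4  # mm Hg systolic drop per extra 1000 steps/day
    bp_max_drop: float = 15.0  # physiological cap on the activity-related BP drop
    bp_noise_sd: float = 4.0
    weight_record_prob: float = 0.95
    weight_slope_per_million: float = 0.5  # kg lost per million extra steps
    weight_noise_sd: float = 0.3
    kcal_per_step: float = 0.028
    kcal_noise_sd: float = 5.0
    seasonal_amplitude: float = 0.0  # optional sinusoid on log steps (off by default)
    questionnaire_missing_prob: float = 0.01

    def __post_init__(self) -> None:
        if self.weeks < 1:
            raise ValidationError("weeks must be >= 1")


@dataclass(frozen=True)
class UserTrajectory:
    user: SimUser
    records: tuple[DailyRecord, ...]
    goal_trace: tuple[GoalState, ...]
    performances: tuple[WeekPerformance, ...]
    se_by_week: tuple[float, ...]  # self-efficacy entering weeks 1..W (index 0 = baseline)
    dropout_week: int | None


@dataclass
class TrialDataset:
    """One complete virtual trial, ready for the evaluation module."""

    participants: list[Participant]
    records: dict[str, list[DailyRecord]]
    goal_traces: dict[str, list[GoalState]]
    questionnaires: dict[str, dict[str, QuestionnaireResponse]]  # pid -> timepoint -> response
    config: SimConfig
    seed: int | None = None

    def baseline_means(self, rule: CleaningRule = CleaningRule()) -> dict[str, float]:
        """Cleaned P0b mean steps/day per participant (absent if no valid days)."""
        period = StudyPeriod.baseline(self.config.baseline_days)
        out: dict[str, float] = {}
        for pid, recs in self.records.items():
            cleaned = clean_step_series(
                window_period(recs, period, self.config.study_start), rule
            )
            if cleaned:
                out[pid] = float(np.mean([r.steps for r in cleaned]))
        return out

    # -- plain-text persistence (CSV/JSONL) ---------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        save_cohort_records(self.records, d / "daily_records.csv")
        with open(d / "goal_traces.jsonl", "w") as fh:
            for pid in sorted(self.goal_traces):
                for gs in self.goal_traces[pid]:
                    fh.write(
                        json.dumps(
                            {
                                "participant_id": pid,
                                "week_index": gs.week_index,
                                "goal": gs.goal,
                                "source": gs.source.value,
                                "confidence": gs.confidence,
                                "days_achieved_prev_week": gs.days_achieved_prev_week,
                            },
                            sort_keys=True,
                        )
                        + "\n"
                    )
        rows = []
        for pid in sorted(self.questionnaires):
            for tp, resp in self.questionnaires[pid].items():
                for instrument, mapping in (
                    ("smbpa", resp.smbpa),
                    ("pasr", resp.pasr),
                    ("goal_confidence", {str(k): v for k, v in resp.goal_confidences.items()}),
                    ("walking", resp.walking),
                    ("pain", resp.pain),
                ):
                    for item, value in mapping.items():
                        rows.append(
                            {
                                "participant_id": pid,
                                "timepoint": tp,
                                "instrument": instrument,
                                "item": str(item),
                                "value": "" if value is None else format(float(value), ".6g"),
                            }
                        )
        pd.DataFrame(
            rows, columns=["participant_id", "timepoint", "instrument", "item", "value"]
        ).to_csv(d / "questionnaires.csv", index=False)
        pd.DataFrame(
            [
                {
                    "participant_id": p.id,
                    "sex": p.sex,
                    "age": "" if p.age is None else format(p.age, ".6g"),
                    "stage_of_change": p.stage_of_change or "",
                    "medication_events": json.dumps(
                        [
                            {"date": e.date.isoformat(), "drug_class": e.drug_class, "change": e.change}
                            for e in p.medication_events
                        ]
                    ),
                }
                for p in sorted(self.participants, key=lambda p: p.id)
            ]
        ).to_csv(d / "participants.csv", index=False)
        meta = {
            "seed": self.seed,
            "weeks": self.config.weeks,
            "baseline_days": self.config.baseline_days,
            "gap_days": self.config.gap_days,
            "study_start": self.config.study_start.isoformat(),
        }
        with open(d / "trial_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, directory, config: SimConfig | None = None) -> "TrialDataset":
        d = Path(directory)
        with open(d / "trial_meta.json") as fh:
            meta = json.load(fh)
        cfg = config or SimConfig(
            weeks=meta["weeks"],
            baseline_days=meta["baseline_days"],
            gap_days=meta["gap_days"],
            study_start=dt.date.fromisoformat(meta["study_start"]),
        )
        records = load_cohort_records(d / "daily_records.csv")
        from .goals import GoalSource  # local import to avoid cycle at module load

        goal_traces: dict[str, list[GoalState]] = {}
        with open(d / "goal_traces.jsonl") as fh:
            for line in fh:
                row = json.loads(line)
                goal_traces.setdefault(row["participant_id"], []).append(
                    GoalState(
                        week_index=row["week_index"],
                        goal=row["goal"],
                        source=GoalSource(row["source"]),
                        confidence=row["confidence"],
                        days_achieved_prev_week=row["days_achieved_prev_week"],
                    )
                )
        qdf = pd.read_csv(d / "questionnaires.csv", dtype=str, keep_default_na=False)
        questionnaires: dict[str, dict[str, QuestionnaireResponse]] = {}
        grouped: dict[tuple[str, str], dict[str, dict]] = {}
        for row in qdf.itertuples(index=False):
            key = (row.participant_id, row.timepoint)
            inst = grouped.setdefault(key, {"smbpa": {}, "pasr": {}, "goal_confidence": {}, "walking": {}, "pain": {}})
            value = None if row.value == "" else float(row.value)
            inst[row.instrument][row.item] = value
        for (pid, tp), inst in grouped.items():
            questionnaires.setdefault(pid, {})[tp] = QuestionnaireResponse(
                smbpa=inst["smbpa"],
                pasr=inst["pasr"],
                goal_confidences={int(k): v for k, v in inst["goal_confidence"].items()},
                walking=inst["walking"],
                pain=inst["pain"],
            )
        pdf = pd.read_csv(d / "participants.csv", dtype=str, keep_default_na=False)
        participants = [
            Participant(
                id=row.participant_id,
                sex=row.sex,
                age=None if row.age == "" else float(row.age),
                stage_of_change=row.stage_of_change or None,
                medication_events=tuple(
                    MedicationEvent(
                        date=dt.date.fromisoformat(e["date"]),
                        drug_class=e["drug_class"],
                        change=e["change"],
                    )
                    for e in json.loads(row.medication_events)
                ),
            )
            for row in pdf.itertuples(index=False)
        ]
        return cls(
            participants=participants,
            records=records,
            goal_traces=goal_traces,
            questionnaires=questionnaires,
            config=cfg,
            seed=meta.get("seed"),
        )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    n: int, config: SimConfig = SimConfig(), seed: int | np.random.Generator = 0
) -> list[SimUser]:
    """Draw ``n`` synthetic users from the population distributions.

    Reproducible under the seed; for n >= 100 the median of simulated P0b
    means lands within ~10% of ``baseline_median_steps``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    pop = config.population
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    users = []
    for i in range(n):
        mu = np.log(pop.baseline_median_steps) + rng.normal(0.0, pop.between_sd_log)
        users.append(
            SimUser(
                id=f"sim{i + 1:03d}",
                baseline_log_mean=float(mu),
                baseline_log_sd=pop.within_sd_log,
                self_efficacy=float(np.clip(rng.normal(pop.self_efficacy_mean, pop.self_efficacy_sd), 0, 100)),
                responsiveness=float(max(0.0, rng.normal(pop.responsiveness_mean, pop.responsiveness_sd))),
                mastery_gain=pop.mastery_gain,
                failure_loss=pop.failure_loss,
                wear_prob=pop.wear_prob,
                dropout_hazard=pop.dropout_hazard,
                sbp_base=float(rng.normal(pop.sbp_mean, pop.sbp_sd)),
                dbp_base=float(rng.normal(pop.dbp_mean, pop.dbp_sd)),
                weight_base=float(rng.normal(pop.weight_mean, pop.weight_sd)),
            )
        )
    return users


# ---------------------------------------------------------------------------
# Single-user trajectory
# ---------------------------------------------------------------------------


def _drive(self_efficacy: float, difficulty: float, config: SimConfig) -> float:
    """Logistic achievement drive in (0, 1): monotone up in self-efficacy,
    down in goal difficulty (goal elevation in increment units).

    Difficulty is floored at zero: a goal at or below the habitual level does
    not push effort above what self-efficacy alone sustains, so eroded
    self-efficacy depresses effort even after the ladder retreats.
    """
    x = (
        self_efficacy
        - config.drive_midpoint
        - config.drive_difficulty_weight * max(0.0, difficulty)
    ) / config.drive_scale
    return float(1.0 / (1.0 + np.exp(-x)))


def simulate_user_weeks(
    user: SimUser,
    config: SimConfig = SimConfig(),
    weeks: int | None = None,
    seed: int | np.random.Generator = 0,
) -> UserTrajectory:
    """Simulate baseline plus ``weeks`` intervention weeks for one user.

    Daily steps are exp(Normal(baseline_log_mean, baseline_log_sd)) plus the
    week's effort term.  Weekly sessions run the real goal engine: the week-1
    suggestion from the cleaned P0b mean, later suggestions from achieved
    days, the confidence negotiation with the user's (noisy) difficulty-bent
    self-efficacy, then a mastery update of self-efficacy from the week's
    outcome.  Non-wear days are flagged ``worn=false`` and carry a partial
    step count; after dropout no further data are recorded.
    """
    weeks = config.weeks if weeks is None else weeks
    if weeks < 1:
        raise ValidationError("weeks must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rule = CleaningRule()
    gc = config.goal
    n_days = config.baseline_days + config.gap_days + 7 * weeks

    z = rng.normal(0.0, 1.0, n_days)
    wear = rng.random(n_days) < user.wear_prob
    bp_present = rng.random(n_days) < config.bp_record_prob
    wt_present = rng.random(n_days) < config.weight_record_prob
    bp_noise = rng.normal(0.0, config.bp_noise_sd, (n_days, 4))
    wt_noise = rng.normal(0.0, config.weight_noise_sd, n_days)
    kcal_noise = rng.normal(0.0, config.kcal_noise_sd, n_days)
    if user.dropout_hazard > 0:
        dropout_week: int | None = int(rng.geometric(user.dropout_hazard))
        if dropout_week > weeks:
            dropout_week = None
    else:
        dropout_week = None

    season = (
        config.seasonal_amplitude * np.sin(2 * np.pi * np.arange(n_days) / 365.25)
        if config.seasonal_amplitude
        else np.zeros(n_days)
    )

    records: list[DailyRecord] = []
    cum_extra = 0.0

    def make_day(day_idx: int, effort: float) -> DailyRecord:
        nonlocal cum_extra
        date = config.study_start + dt.timedelta(days=day_idx)
        raw = float(
            np.exp(user.baseline_log_mean + user.baseline_log_sd * z[day_idx] + season[day_idx])
        )
        true_steps = max(0.0, raw + effort)
        cum_extra += effort
        worn = bool(wear[day_idx])
        steps = int(round(true_steps if worn else config.nonwear_step_fraction * true_steps))
        activity_drop = min(config.bp_max_drop, config.bp_slope_per_1000 * effort / 1000.0)
        weight = (
            user.weight_base
            - config.weight_slope_per_million * cum_extra / 1e6
            + wt_noise[day_idx]
        )
        return DailyRecord(
            date=date,
            steps=steps,
            worn=worn,
            sbp_m=round(user.sbp_base - activity_drop + bp_noise[day_idx, 0], 1)
            if bp_present[day_idx]
            else None,
            dbp_m=round(user.dbp_base - 0.5 * activity_drop + bp_noise[day_idx, 1], 1)
            if bp_present[day_idx]
            else None,
            sbp_n=round(user.sbp_base - 6.0 - activity_drop + bp_noise[day_idx, 2], 1)
            if bp_present[day_idx]
            else None,
            dbp_n=round(user.dbp_base - 4.0 - 0.5 * activity_drop + bp_noise[day_idx, 3], 1)
            if bp_present[day_idx]
            else None,
            weight_kg=round(weight, 1) if wt_present[day_idx] else None,
            kcal_activity=round(max(0.0, config.kcal_per_step * steps + kcal_noise[day_idx]), 1),
        )

    def missing_day(day_idx: int) -> DailyRecord:
        return DailyRecord(date=config.study_start + dt.timedelta(days=day_idx))

    for day in range(config.baseline_days + config.gap_days):
        records.append(make_day(day, 0.0))

    baseline = clean_step_series(records[: config.baseline_days], rule)
    p0b_mean = float(np.mean([r.steps for r in baseline])) if baseline else float(
        np.exp(user.baseline_log_mean)
    )

    se = user.self_efficacy
    se_by_week: list[float] = [se]
    goal_trace: list[GoalState] = []
    performances: list[WeekPerformance] = []
    prev_state: GoalState | None = None
    prev_perf: WeekPerformance | None = None
    day0 = config.baseline_days + config.gap_days

    for week in range(1, weeks + 1):
        if dropout_week is not None and week >= dropout_week:
            for d in range(7):
                records.append(missing_day(day0 + 7 * (week - 1) + d))
            continue

        if prev_state is None:
            suggestion = suggest_week1_goal(p0b_mean, gc)
        else:
            suggestion = suggest_next_goal(prev_state, prev_perf, gc)

        def confidence_of(goal: int) -> float:
            difficulty = (goal - p0b_mean) / gc.increment
            noisy = (
                se
                - config.conf_difficulty_weight * difficulty
                + rng.normal(0.0, config.conf_noise_sd)
            )
            return float(np.clip(noisy, 0.0, 100.0))

        proposal, confidence, _verdict, nego_log = negotiate_goal(suggestion, confidence_of, gc)
        state = finalize_goal(
            proposal,
            None,
            gc,
            week_index=week,
            adjusted=len(nego_log) > 1,
            confidence=confidence,
            days_achieved_prev_week=prev_perf.days_achieved if prev_perf else None,
        )
        goal_trace.append(state)

        difficulty = (state.goal - p0b_mean) / gc.increment
        effort = user.responsiveness * _drive(se, difficulty, config)
        week_records = [make_day(day0 + 7 * (week - 1) + d, effort) for d in range(7)]
        records.extend(week_records)

        valid = clean_step_series(week_records, rule)
        mean_steps = float(np.mean([r.steps for r in valid])) if valid else 0.0
        days_achieved = sum(1 for r in valid if r.steps >= state.goal)
        perf = WeekPerformance(mean_steps=mean_steps, days_achieved=days_achieved, goal=state.goal)
        performances.append(perf)

        met = days_achieved >= gc.raise_threshold_days
        se = float(np.clip(se + (user.mastery_gain if met else -user.failure_loss), 0.0, 100.0))
        se_by_week.append(se)
        prev_state, prev_perf = state, perf

    return UserTrajectory(
        user=user,
        records=tuple(records),
        goal_trace=tuple(goal_trace),
        performances=tuple(performances),
        se_by_week=tuple(se_by_week),
        dropout_week=dropout_week,
    )


# ---------------------------------------------------------------------------
# Whole-trial simulation
# ---------------------------------------------------------------------------


def _binomial_items(rng, prefix: str, counts, n_levels: int, p: float, base: int, miss: float):
    out = {}
    items = (
        [f"{prefix}_{i + 1}" for i in range(counts)]
        if isinstance(counts, int)
        else [f"{f}_{i + 1}" for f, c in counts.items() for i in range(c)]
    )
    for item in items:
        if rng.random() < miss:
            out[item] = None
        else:
            out[item] = int(base + rng.binomial(n_levels - 1, p))
    return out


def _questionnaire(rng, se: float, engagement: float, config: SimConfig) -> QuestionnaireResponse:
    """Plausible responses given current self-efficacy and system engagement.

    Goal confidence falls with the goal level around the user's self-efficacy;
    self-regulation and self-management frequencies rise with engagement
    (using the system exercises exactly those behaviors).
    """
    miss = config.questionnaire_missing_prob
    confs = {
        g: float(np.clip(se + 18.0 - 9.0 * (g - 6000) / 2000.0 + rng.normal(0, 6), 0, 100))
        for g in GOAL_LEVELS
    }
    pasr = _binomial_items(rng, "", dict.fromkeys(PASR_FACTORS, 2), 5, 0.18 + 0.25 * engagement, 1, 0.0)
    smbpa = _binomial_items(rng, "", dict(SMBPA_FACTORS), 5, 0.18 + 0.20 * engagement, 0, miss)
    walking = _binomial_items(rng, "walking", 4, 5, 0.30 + 0.10 * engagement, 1, 0.0)
    pain = _binomial_items(rng, "pain", 4, 5, 0.08, 0, 0.0)
    return QuestionnaireResponse(
        smbpa=smbpa, pasr=pasr, goal_confidences=confs, walking=walking, pain=pain
    )


def run_trial(
    cohort: Sequence[SimUser],
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> TrialDataset:
    """Simulate the full study for a cohort: baseline P0b, the intervention
    weeks, weekly goal traces, and questionnaires at P0a / P1a / P2a.

    One seed fans out to per-user child generators through a SeedSequence, so
    any user's trajectory is independently reproducible.
    """
    if not cohort:
        raise ValidationError("cohort must be non-empty")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(cohort) + 1)
    demo_rng = np.random.default_rng(children[0])

    participants: list[Participant] = []
    records: dict[str, list[DailyRecord]] = {}
    goal_traces: dict[str, list[GoalState]] = {}
    questionnaires: dict[str, dict[str, QuestionnaireResponse]] = {}
    stages = list(config.population.stage_probs)
    stage_p = np.array([config.population.stage_probs[s] for s in stages])
    mid_week = min(6, config.weeks)

    for user, child in zip(cohort, children[1:]):
        rng = np.random.default_rng(child)
        traj = simulate_user_weeks(user, config, config.weeks, rng)
        records[user.id] = list(traj.records)
        goal_traces[user.id] = list(traj.goal_trace)

        events: tuple[MedicationEvent, ...] = ()
        if demo_rng.random() < config.population.new_bp_med_prob:
            week = int(demo_rng.integers(1, config.weeks + 1))
            events = (
                MedicationEvent(
                    date=config.study_start
                    + dt.timedelta(days=config.baseline_days + config.gap_days + 7 * (week - 1)),
                    drug_class="hypertension",
                    change=str(demo_rng.choice(["start", "increase"])),
                ),
            )
        participants.append(
            Participant(
                id=user.id,
                sex=str(demo_rng.choice(["male", "female"], p=[0.63, 0.37])),
                age=float(np.clip(demo_rng.normal(52.9, 5.3), 25, 70)),
                stage_of_change=str(demo_rng.choice(stages, p=stage_p)),
                medication_events=events,
            )
        )
        se0 = traj.se_by_week[0]
        se_mid = traj.se_by_week[min(mid_week, len(traj.se_by_week) - 1)]
        se_end = traj.se_by_week[-1]
        questionnaires[user.id] = {
            "P0a": _questionnaire(rng, se0, 0.0, config),
            "P1a": _questionnaire(rng, se_mid, 1.0, config),
            "P2a": _questionnaire(rng, se_end, 1.0, config),
        }

    return TrialDataset(
        participants=participants,
        records=records,
        goal_traces=goal_traces,
        questionnaires=questionnaires,
        config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------


def load_sim_config(path) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file.

    Top-level keys map to SimConfig fields; ``population`` and ``goal`` are
    nested mappings for :class:`PopulationConfig` and GoalConfig fields.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    pop = PopulationConfig(**data.pop("population", {}))
    goal = GoalConfig(**data.pop("goal", {}))
    if "study_start" in data:
        data["study_start"] = dt.date.fromisoformat(str(data["study_start"]))
    known = set(asdict(SimConfig()).keys())
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown sim-config field(s) {sorted(unknown)}")
    return SimConfig(population=pop, goal=goal, **data)
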