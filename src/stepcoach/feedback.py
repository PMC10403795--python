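"""Daily and weekly feedback message selection.

Positive feedback is the verbal-persuasion arm of the intervention: a daily
message about step-goal achievement, a behavior-specific message keyed to the
user's self-management-behavior profile (the 32-item, 9-factor ES-SMBPA-2D
frequency scale), and a weekly summary with per-parameter change messages.

On a missed-goal day the engine recommends one of the behaviors the user
reports doing "never" or "rarely"; on an achieved-goal day it praises one of
the behaviors done "often" or "always".  Eligible messages are drawn
uniformly under a seeded generator, avoiding an immediate repeat of the
previous advice/praise when at least two are eligible, so a fixed seed yields
a byte-identical transcript.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import CatalogError, ValidationError
from .goals import GoalState
from .records import PeriodSummary

__all__ = [
    "SMBPA_FACTORS",
    "SMBPA_ITEMS",
    "FREQUENCY_LEVELS",
    "MessageKind",
    "MessageEntry",
    "MessageCatalog",
    "BehaviorResponse",
    "WeeklyFeedback",
    "ChangeTolerances",
    "daily_goal_feedback",
    "select_behavior_advice",
    "select_behavior_praise",
    "compose_weekly_feedback",
]

#: 5-level frequency scale; item scores are the 0..4 indices of these labels.
FREQUENCY_LEVELS = ("never", "rarely", "sometimes", "often", "always")

#: ES-SMBPA-2D structure: factor -> number of items.  Factor scores are item
#: sums, so the ranges are 0-16, 0-16, 0-16, 0-16, 0-20, 0-12, 0-12, 0-8, 0-12.
SMBPA_FACTORS: dict[str, int] = {
    "shopping": 4,
    "household": 4,
    "exertion": 4,
    "commuting": 4,
    "place_time": 5,
    "self_monitoring": 3,
    "habit": 3,
    "eat_exercise": 2,
    "situation": 3,
}

#: Item id -> short behavior description (fixture text in English).
SMBPA_ITEMS: dict[str, str] = {
    "shopping_1": "walk to a nearby shop instead of driving",
    "shopping_2": "choose a store a little farther away on foot",
    "shopping_3": "carry a basket rather than pushing a cart",
    "shopping_4": "add an extra loop of errands on foot",
    "household_1": "do housework briskly and actively",
    "household_2": "spend time gardening or yard work",
    "household_3": "clean one extra room each day",
    "household_4": "use the stairs at home whenever possible",
    "exertion_1": "walk briskly rather than strolling",
    "exertion_2": "take a deliberately longer walking route",
    "exertion_3": "take the stairs instead of the elevator",
    "exertion_4": "get off the bus or train one stop early",
    "commuting_1": "walk part of the commute",
    "commuting_2": "run small errands on foot or by bicycle",
    "commuting_3": "park farther from the entrance",
    "commuting_4": "take a short walk during work breaks",
    "place_time_1": "set aside a regular time for walking",
    "place_time_2": "pick a safe and pleasant walking route",
    "place_time_3": "use a park or gym for activity",
    "place_time_4": "have an indoor alternative for bad weather",
    "place_time_5": "plan activity around the week's schedule",
    "self_monitoring_1": "check the day's step count",
    "self_monitoring_2": "record physical activity",
    "self_monitoring_3": "review the weekly activity trend",
    "habit_1": "walk at the same time every day",
    "habit_2": "tie walking to an existing daily routine",
    "habit_3": "keep walking shoes and clothes ready",
    "eat_exercise_1": "take a walk after a large meal",
    "eat_exercise_2": "exercise to enjoy meals more",
    "situation_1": "invite family or friends to walk together",
    "situation_2": "set reminders to move",
    "situation_3": "keep activity equipment in sight",
}

assert sum(SMBPA_FACTORS.values()) == 32 == len(SMBPA_ITEMS)


def smbpa_factor_of(item_id: str) -> str:
    factor = item_id.rsplit("_", 1)[0]
    if factor not in SMBPA_FACTORS:
        raise ValidationError(f"unknown ES-SMBPA-2D item {item_id!r}")
    return factor


class MessageKind(str, Enum):
    DAILY_ACHIEVED = "daily_achieved"
    DAILY_MISSED = "daily_missed"
    BEHAVIOR_ADVICE = "behavior_advice"
    BEHAVIOR_PRAISE = "behavior_praise"
    WEEKLY_CHANGE = "weekly_change"


@dataclass(frozen=True)
class MessageEntry:
    id: str
    kind: MessageKind
    text: str
    linked_item: str | None = None  # ES-SMBPA-2D item id for advice/praise
    params: Mapping[str, str] = field(default_factory=dict)  # applicability predicate


_GENERIC_ADVICE_ID = "advice-generic"
_GENERIC_PRAISE_ID = "praise-generic"


@dataclass(frozen=True)
class MessageCatalog:
    entries: tuple[MessageEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(f"duplicate message id(s): {dupes}")
        for e in self.entries:
            if e.kind in (MessageKind.BEHAVIOR_ADVICE, MessageKind.BEHAVIOR_PRAISE):
                # the generic fallbacks are the only unlinked advice/praise entries
                if e.linked_item is None:
                    if e.id not in (_GENERIC_ADVICE_ID, _GENERIC_PRAISE_ID):
                        raise CatalogError(f"{e.id}: advice/praise must link to an item")
                elif e.linked_item not in SMBPA_ITEMS:
                    raise CatalogError(f"{e.id}: unknown linked item {e.linked_item!r}")

    def by_id(self, message_id: str) -> MessageEntry:
        for e in self.entries:
            if e.id == message_id:
                return e
        raise CatalogError(f"no message with id {message_id!r}")

    def of_kind(self, kind: MessageKind) -> list[MessageEntry]:
        return [e for e in self.entries if e.kind == kind]

    def to_json(self, path) -> None:
        data = [
            {
                "id": e.id,
                "kind": e.kind.value,
                "text": e.text,
                "linked_item": e.linked_item,
                "params": dict(e.params),
            }
            for e in self.entries
        ]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "MessageCatalog":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            tuple(
                MessageEntry(
                    id=d["id"],
                    kind=MessageKind(d["kind"]),
                    text=d["text"],
                    linked_item=d.get("linked_item"),
                    params=d.get("params", {}),
                )
                for d in data
            )
        )

    @classmethod
    def default(cls) -> "MessageCatalog":
        """Shipped fixture catalog: English placeholder texts keyed to the
        behavior items and parameter change classes."""
        entries: list[MessageEntry] = []
        for i, text in enumerate(
            (
                "Goal achieved - great work today!",
                "You reached your step goal. Keep the momentum going!",
                "Another goal met. Your consistency is paying off.",
            ),
            1,
        ):
            entries.append(MessageEntry(f"daily-achieved-{i}", MessageKind.DAILY_ACHIEVED, text))
        for i, text in enumerate(
            (
                "Not quite there today - tomorrow is a fresh start.",
                "A short walk this evening could close the gap next time.",
                "Every step counts; see what gets in the way and plan around it.",
            ),
            1,
        ):
            entries.append(MessageEntry(f"daily-missed-{i}", MessageKind.DAILY_MISSED, text))
        for item_id, behavior in SMBPA_ITEMS.items():
            entries.append(
                MessageEntry(
                    f"advice-{item_id}",
                    MessageKind.BEHAVIOR_ADVICE,
                    f"Why not try to {behavior}? It can add steps to your day.",
                    linked_item=item_id,
                )
            )
            entries.append(
                MessageEntry(
                    f"praise-{item_id}",
                    MessageKind.BEHAVIOR_PRAISE,
                    f"You regularly {behavior} - that habit is helping you. Keep it up!",
                    linked_item=item_id,
                )
            )
        entries.append(
            MessageEntry(
                _GENERIC_ADVICE_ID,
                MessageKind.BEHAVIOR_ADVICE,
                "Look for one small chance to walk a little more tomorrow.",
            )
        )
        entries.append(
            MessageEntry(
                _GENERIC_PRAISE_ID,
                MessageKind.BEHAVIOR_PRAISE,
                "You are building solid activity habits. Keep it up!",
            )
        )
        phrases = {"up": "increased", "down": "decreased", "stable": "stayed stable"}
        for parameter in (
            "steps",
            "kcal",
            "sbp_morning",
            "dbp_morning",
            "sbp_night",
            "dbp_night",
            "weight",
            "glucose",
        ):
            for direction, phrase in phrases.items():
                entries.append(
                    MessageEntry(
                        f"weekly-{parameter}-{direction}",
                        MessageKind.WEEKLY_CHANGE,
                        f"Your {parameter.replace('_', ' ')} {phrase} compared with last week.",
                        params={"parameter": parameter, "direction": direction},
                    )
                )
        return cls(tuple(entries))


@dataclass(frozen=True)
class BehaviorResponse:
    """One administration of the 32-item behavior-frequency scale.

    ``scores`` maps every item id to 0..4 (never..always) or ``None`` for an
    explicitly missing response.
    """

    scores: Mapping[str, int | None]

    def __post_init__(self) -> None:
        missing = set(SMBPA_ITEMS) - set(self.scores)
        if missing:
            raise ValidationError(f"response lacks item(s): {sorted(missing)[:5]} ...")
        unknown = set(self.scores) - set(SMBPA_ITEMS)
        if unknown:
            raise ValidationError(f"unknown item(s): {sorted(unknown)[:5]}")
        for item, score in self.scores.items():
            if score is not None and score not in range(5):
                raise ValidationError(f"{item}: score {score} outside 0..4")

    def items_at(self, levels: Sequence[int]) -> list[str]:
        return sorted(i for i, s in self.scores.items() if s in levels)


@dataclass(frozen=True)
class ChangeTolerances:
    """No-change bands for weekly per-parameter messages (paper-silent;
    defaults avoid jitter-driven messages)."""

    bp_mmhg: float = 1.0
    weight_kg: float = 0.2
    steps_per_day: float = 200.0
    kcal_per_day: float = 20.0
    glucose_mgdl: float = 5.0

    def for_parameter(self, parameter: str) -> float:
        if parameter in ("sbp_morning", "dbp_morning", "sbp_night", "dbp_night"):
            return self.bp_mmhg
        return {
            "steps": self.steps_per_day,
            "kcal": self.kcal_per_day,
            "weight": self.weight_kg,
            "glucose": self.glucose_mgdl,
        }[parameter]


@dataclass(frozen=True)
class WeeklyFeedback:
    week_index: int
    mean_steps: float | None
    days_achieved: int
    goal: int
    parameter_means: Mapping[str, float]
    change_messages: Mapping[str, str]  # parameter -> message id

    def __post_init__(self) -> None:
        if not (0 <= self.days_achieved <= 7):
            raise ValidationError("days_achieved must be in 0..7")


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def daily_goal_feedback(steps: int, goal: int, catalog: MessageCatalog, rng_seed) -> str:
    """Achievement message iff steps >= goal (meeting the goal counts), else a
    missed-goal message; uniform over the kind's entries under the seed."""
    kind = MessageKind.DAILY_ACHIEVED if steps >= goal else MessageKind.DAILY_MISSED
    pool = catalog.of_kind(kind)
    if not pool:
        raise CatalogError(f"catalog has no {kind.value} messages")
    rng = _as_rng(rng_seed)
    return pool[int(rng.integers(len(pool)))].id


def _select_linked(
    response: BehaviorResponse,
    catalog: MessageCatalog,
    rng_seed,
    kind: MessageKind,
    levels: Sequence[int],
    fallback_id: str,
    previous_id: str | None,
) -> str:
    eligible_items = set(response.items_at(levels))
    pool = [
        e
        for e in catalog.of_kind(kind)
        if e.linked_item is not None and e.linked_item in eligible_items
    ]
    if not pool:
        return catalog.by_id(fallback_id).id
    if previous_id is not None and len(pool) >= 2:
        pool = [e for e in pool if e.id != previous_id] or pool
    rng = _as_rng(rng_seed)
    return pool[int(rng.integers(len(pool)))].id


def select_behavior_advice(
    response: BehaviorResponse,
    catalog: MessageCatalog,
    rng_seed,
    previous_id: str | None = None,
) -> str:
    """Recommend a behavior the user does never/rarely (missed-goal days).

    Uniform among eligible advice entries; avoids repeating ``previous_id``
    when at least two are eligible; generic encouragement if none qualify.
    """
    return _select_linked(
        response, catalog, rng_seed, MessageKind.BEHAVIOR_ADVICE, (0, 1), _GENERIC_ADVICE_ID, previous_id
    )


def select_behavior_praise(
    response: BehaviorResponse,
    catalog: MessageCatalog,
    rng_seed,
    previous_id: str | None = None,
) -> str:
    """Recognize a behavior the user does often/always (achieved-goal days)."""
    return _select_linked(
        response, catalog, rng_seed, MessageKind.BEHAVIOR_PRAISE, (3, 4), _GENERIC_PRAISE_ID, previous_id
    )


_SUMMARY_PARAMS = {
    "steps": "mean_steps",
    "kcal": "mean_kcal",
    "sbp_morning": "sbp_morning",
    "dbp_morning": "dbp_morning",
    "sbp_night": "sbp_night",
    "dbp_night": "dbp_night",
    "weight": "weight",
    "glucose": "glucose",
}


def compose_weekly_feedback(
    this_week: PeriodSummary,
    prev_week: PeriodSummary | None,
    goal_state: GoalState,
    catalog: MessageCatalog,
    days_achieved: int,
    tolerances: ChangeTolerances = ChangeTolerances(),
) -> WeeklyFeedback:
    """Weekly summary: mean steps, achieved days vs goal, parameter means, and
    one change message per parameter with data in both weeks.

    Direction is the sign of (this week - last week) outside the parameter's
    no-change tolerance.  In the first week of use (no previous summary) the
    change messages are omitted while the means are still reported.
    """
    means: dict[str, float] = {}
    changes: dict[str, str] = {}
    for parameter, attr in _SUMMARY_PARAMS.items():
        now = getattr(this_week, attr)
        if now is None:
            continue
        means[parameter] = now
        if prev_week is None:
            continue
        before = getattr(prev_week, attr)
        if before is None:
            continue
        delta = now - before
        tol = tolerances.for_parameter(parameter)
        direction = "stable" if abs(delta) <= tol else ("up" if delta > 0 else "down")
        matches = [
            e
            for e in catalog.of_kind(MessageKind.WEEKLY_CHANGE)
            if e.params.get("parameter") == parameter and e.params.get("direction") == direction
        ]
        if not matches:
            raise CatalogError(f"no weekly_change message for {parameter}/{direction}")
        changes[parameter] = matches[0].id
    return WeeklyFeedback(
        week_index=goal_state.week_index,
        mean_steps=this_week.mean_steps,
        days_achieved=days_achieved,
        goal=goal_state.goal,
        parameter_means=means,
        change_messages=changes,
    )
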