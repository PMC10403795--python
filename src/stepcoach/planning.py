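"""Weekly action planning and barrier identification / problem-solving.

After the step goal is set, the weekly session routes to one of three
activities based on the past week's performance: users who clearly met their
goal think ahead about *future* barriers (relapse prevention), users who
clearly struggled rate their *current* barriers and pick solutions, and
everyone else reviews their action plan.  The action list holds 12 predefined
actions for increasing step count plus a free-text slot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .errors import CatalogError, ValidationError
from .goals import WeekPerformance

__all__ = [
    "SessionRoute",
    "RoutingConfig",
    "ActionItem",
    "ActionCatalog",
    "Barrier",
    "BarrierCatalog",
    "ActionPlan",
    "PlanLog",
    "route_weekly_session",
    "build_action_plan",
    "elicit_barrier_solutions",
]


class SessionRoute(str, Enum):
    REVIEW_PLAN = "review_plan"
    CURRENT_BARRIERS = "current_barriers"
    FUTURE_BARRIERS = "future_barriers"


@dataclass(frozen=True)
class RoutingConfig:
    """Cutoffs for the weekly routing rule (all configurable; the deployed
    system's exact conditionals are not public)."""

    success_days: int = 4  # achieved days/week counting as clear success
    failure_days_max: int = 1  # achieved days/week counting as clear struggle
    failure_mean_fraction: float = 0.8  # mean below this fraction of goal = struggle

    def __post_init__(self) -> None:
        if not (0 <= self.failure_days_max < self.success_days <= 7):
            raise ValidationError("need 0 <= failure_days_max < success_days <= 7")
        if not (0 < self.failure_mean_fraction <= 1):
            raise ValidationError("failure_mean_fraction must be in (0, 1]")


def route_weekly_session(
    perf: WeekPerformance, config: RoutingConfig = RoutingConfig()
) -> SessionRoute:
    """Total, single-valued routing over all (mean_steps, days_achieved).

    Clear success (>= ``success_days`` achieved AND mean >= goal) routes to
    future barriers; clear struggle (<= ``failure_days_max`` achieved OR mean
    below ``failure_mean_fraction`` x goal) routes to current barriers;
    otherwise the action plan is reviewed.
    """
    if perf.days_achieved >= config.success_days and perf.mean_steps >= perf.goal:
        return SessionRoute.FUTURE_BARRIERS
    if (
        perf.days_achieved <= config.failure_days_max
        or perf.mean_steps < config.failure_mean_fraction * perf.goal
    ):
        return SessionRoute.CURRENT_BARRIERS
    return SessionRoute.REVIEW_PLAN


@dataclass(frozen=True)
class ActionItem:
    id: str
    text: str


@dataclass(frozen=True)
class ActionCatalog:
    """The predefined action list (12 entries in the shipped fixture)."""

    items: tuple[ActionItem, ...]

    def __post_init__(self) -> None:
        ids = [a.id for a in self.items]
        if len(ids) != len(set(ids)):
            raise CatalogError("duplicate action ids")

    def ids(self) -> set[str]:
        return {a.id for a in self.items}

    @classmethod
    def default(cls) -> "ActionCatalog":
        texts = (
            "Take the stairs instead of the elevator or escalator",
            "Get off the bus or train one stop early and walk",
            "Walk to a farther shop, cafe, or lunch spot",
            "Take a 10-minute walk during the lunch break",
            "Park the car or bicycle farther from the entrance",
            "Walk while talking on the phone",
            "Take a short walk after dinner",
            "Walk the whole or part of the commute",
            "Use a restroom or printer on another floor",
            "Plan a weekend walk in a park or new neighborhood",
            "Walk with a family member, friend, or colleague",
            "Do errands on foot instead of online or by car",
        )
        return cls(tuple(ActionItem(f"a{i + 1}", t) for i, t in enumerate(texts)))


@dataclass(frozen=True)
class Barrier:
    id: str
    text: str
    kind: str  # "current" | "future"
    solution_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("current", "future"):
            raise ValidationError(f"{self.id}: kind must be current or future")


@dataclass(frozen=True)
class BarrierCatalog:
    """Common barriers to walking with canned solutions (every barrier has at
    least one solution)."""

    barriers: tuple[Barrier, ...]
    solutions: Mapping[str, str]  # solution id -> text

    def __post_init__(self) -> None:
        ids = [b.id for b in self.barriers]
        if len(ids) != len(set(ids)):
            raise CatalogError("duplicate barrier ids")
        for b in self.barriers:
            if not b.solution_ids:
                raise CatalogError(f"barrier {b.id} has no solutions")
            for s in b.solution_ids:
                if s not in self.solutions:
                    raise CatalogError(f"barrier {b.id}: unknown solution {s!r}")

    def by_id(self, barrier_id: str) -> Barrier:
        for b in self.barriers:
            if b.id == barrier_id:
                return b
        raise ValidationError(f"unknown barrier {barrier_id!r}")

    def of_kind(self, kind: str) -> list[Barrier]:
        return [b for b in self.barriers if b.kind == kind]

    @classmethod
    def default(cls) -> "BarrierCatalog":
        solutions = {
            "s_indoor": "walk indoors (mall, station concourse, stairs at home)",
            "s_gear": "keep rain gear and walkable shoes ready",
            "s_split": "split walking into several short bouts",
            "s_calendar": "block a fixed walking slot in the calendar",
            "s_lunch": "use part of the lunch break for a walk",
            "s_early": "get off transport one stop early",
            "s_rest": "walk at an easy pace and rest as needed",
            "s_sleep": "go to bed earlier to recover energy",
            "s_buddy": "arrange to walk with someone",
            "s_track": "review the step graph to see progress",
            "s_reward": "set a small reward for a week of goals met",
            "s_route": "try a new route or listen to music or podcasts",
            "s_plan_b": "prepare a backup plan for busy days",
            "s_small_goal": "temporarily lower the goal rather than stop",
            "s_doctor": "ask a clinician how to stay active safely",
            "s_family_walk": "turn family time into walking time",
        }
        barriers = (
            Barrier("cb_weather", "Bad weather (rain, heat, cold)", "current", ("s_indoor", "s_gear")),
            Barrier("cb_workload", "Too busy with work", "current", ("s_split", "s_lunch", "s_early")),
            Barrier("cb_fatigue", "Feeling tired", "current", ("s_rest", "s_sleep", "s_split")),
            Barrier("cb_time", "No free time in the day", "current", ("s_calendar", "s_split", "s_early")),
            Barrier("cb_motivation", "Low motivation", "current", ("s_buddy", "s_track", "s_reward", "s_route")),
            Barrier("cb_boredom", "Walking feels boring", "current", ("s_route", "s_buddy")),
            Barrier("cb_pain", "Pain or physical discomfort", "current", ("s_rest", "s_doctor", "s_small_goal")),
            Barrier("cb_family", "Family obligations", "current", ("s_family_walk", "s_split")),
            Barrier("fb_season", "Coming season with bad weather", "future", ("s_indoor", "s_gear")),
            Barrier("fb_holidays", "Holidays or schedule changes ahead", "future", ("s_plan_b", "s_calendar")),
            Barrier("fb_busy_period", "A busy period at work coming up", "future", ("s_plan_b", "s_split", "s_lunch")),
            Barrier("fb_travel", "Travel or work transfer", "future", ("s_plan_b", "s_route")),
            Barrier("fb_injury", "Risk of injury or worsening pain", "future", ("s_small_goal", "s_doctor")),
            Barrier("fb_burnout", "Losing interest after reaching the goal", "future", ("s_reward", "s_buddy", "s_track")),
        )
        return cls(barriers, solutions)


@dataclass(frozen=True)
class ActionPlan:
    week_index: int
    chosen_ids: tuple[str, ...] = ()
    free_texts: tuple[str, ...] = ()


class PlanLog:
    """Stores one plan per week so next week's session can review it."""

    def __init__(self) -> None:
        self._plans: dict[int, ActionPlan] = {}

    def record(self, plan: ActionPlan) -> None:
        self._plans[plan.week_index] = plan

    def review(self, week_index: int) -> ActionPlan | None:
        return self._plans.get(week_index)


def build_action_plan(
    week_index: int,
    chosen_ids: Sequence[str],
    free_texts: Sequence[str],
    catalog: ActionCatalog,
) -> ActionPlan:
    """Validate chosen ids against the catalog and assemble the week's plan
    (an empty plan is allowed)."""
    unknown = [i for i in chosen_ids if i not in catalog.ids()]
    if unknown:
        raise ValidationError(f"unknown action id(s): {unknown}")
    return ActionPlan(week_index, tuple(chosen_ids), tuple(free_texts))


def elicit_barrier_solutions(
    barrier_ids: Sequence[str],
    catalog: BarrierCatalog,
    session_kind: str,
) -> list[tuple[str, tuple[str, ...]]]:
    """Pair each selected barrier with its full solution list, order preserved.

    ``session_kind`` ("current" or "future") must match the routed list; a
    barrier from the other list is a routing-consistency error.
    """
    if session_kind not in ("current", "future"):
        raise ValidationError("session_kind must be 'current' or 'future'")
    out: list[tuple[str, tuple[str, ...]]] = []
    for bid in barrier_ids:
        b = catalog.by_id(bid)
        if b.kind != session_kind:
            raise ValidationError(
                f"barrier {bid} belongs to the {b.kind} list, not this {session_kind}-barriers session"
            )
        out.append((bid, b.solution_ids))
    return out


def save_action_catalog(catalog: ActionCatalog, path) -> None:
    with open(path, "w") as fh:
        json.dump([{"id": a.id, "text": a.text} for a in catalog.items], fh, indent=1)


def load_action_catalog(path) -> ActionCatalog:
    with open(path) as fh:
        return ActionCatalog(tuple(ActionItem(d["id"], d["text"]) for d in json.load(fh)))
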