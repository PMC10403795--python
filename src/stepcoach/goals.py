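"""Weekly step-goal engine: suggestion, confidence assessment, adjustment.

The engine suggests a weekly step goal, the user reports their confidence
(0-100%) of achieving it on more than half the days of the week, and the
goal is adjusted until the confidence falls in the "challenging yet
attainable" band (70-90% inclusive) or the adjustment budget is spent.  The
user may also self-set a goal, subject to the same 15,000 steps/day cap that
applies to system suggestions.

The week-1 suggestion is anchored to the baseline (P0b) mean: round to the
nearest 100 steps and add one increment (500 steps by default).  From week 2
onward the suggestion ladders on the number of days the previous week's goal
was achieved: raise by one increment at >=4 achieved days, hold at 2-3,
lower at <=1.  All thresholds live in :class:`GoalConfig`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from enum import Enum
from typing import Callable

from .errors import ValidationError

__all__ = [
    "GoalConfig",
    "GoalState",
    "GoalSource",
    "WeekPerformance",
    "Verdict",
    "suggest_week1_goal",
    "suggest_next_goal",
    "assess_confidence",
    "adjust_goal",
    "finalize_goal",
    "negotiate_goal",
    "load_goal_config",
]


class Verdict(str, Enum):
    APPROPRIATE = "appropriate"
    TOO_LOW = "too_low"
    TOO_HIGH = "too_high"


class GoalSource(str, Enum):
    SUGGESTED = "suggested"
    SELF_SET = "self_set"
    ADJUSTED = "adjusted"


@dataclass(frozen=True)
class GoalConfig:
    """Tunable goal-ladder parameters (steps/day unless noted)."""

    max_goal: int = 15_000
    floor: int = 2_000
    increment: int = 500
    rounding: int = 100
    confidence_low: float = 70.0  # inclusive lower edge of the appropriate band (%)
    confidence_high: float = 90.0  # inclusive upper edge (%)
    raise_threshold_days: int = 4  # achieved days/week to raise the goal
    hold_min_days: int = 2  # achieved days/week to hold (lower edge)
    max_adjust_rounds: int = 2  # adjust-reassess iterations per weekly session

    def __post_init__(self) -> None:
        if not self.floor < self.max_goal:
            raise ValidationError("floor must be below max_goal")
        if self.increment <= 0 or self.rounding <= 0:
            raise ValidationError("increment and rounding must be positive")
        if not (0 <= self.confidence_low <= self.confidence_high <= 100):
            raise ValidationError("confidence band must satisfy 0 <= low <= high <= 100")
        if not (0 <= self.hold_min_days <= self.raise_threshold_days <= 7):
            raise ValidationError("day thresholds must satisfy 0 <= hold_min <= raise <= 7")

    def clamp(self, goal: float) -> int:
        return int(min(self.max_goal, max(self.floor, goal)))


@dataclass(frozen=True)
class GoalState:
    """The goal in force for one intervention week and how it was arrived at."""

    week_index: int
    goal: int
    source: GoalSource
    confidence: float | None = None
    days_achieved_prev_week: int | None = None

    def __post_init__(self) -> None:
        if self.week_index < 1:
            raise ValidationError("week_index must be >= 1")
        if self.confidence is not None and not (0 <= self.confidence <= 100):
            raise ValidationError("confidence must be in [0, 100]")
        if self.days_achieved_prev_week is not None and not (
            0 <= self.days_achieved_prev_week <= 7
        ):
            raise ValidationError("days_achieved_prev_week must be in 0..7")


@dataclass(frozen=True)
class WeekPerformance:
    """Observed performance over one completed intervention week."""

    mean_steps: float
    days_achieved: int
    goal: int

    def __post_init__(self) -> None:
        if not (0 <= self.days_achieved <= 7):
            raise ValidationError("days_achieved must be in 0..7")


def _round_to(step: int, x: float) -> int:
    # round half up, e.g. 10,020 -> 10,000 and 10,050 -> 10,100 at step 100
    return int(math.floor(x / step + 0.5) * step)


def suggest_week1_goal(baseline_mean_steps: float, config: GoalConfig = GoalConfig()) -> int:
    """First-week suggestion: baseline mean rounded to ``rounding`` plus one
    increment, clamped to [floor, max_goal]."""
    if baseline_mean_steps <= 0:
        raise ValidationError(f"baseline mean must be positive, got {baseline_mean_steps}")
    return config.clamp(_round_to(config.rounding, baseline_mean_steps) + config.increment)


def suggest_next_goal(
    prev: GoalState, perf: WeekPerformance, config: GoalConfig = GoalConfig()
) -> int:
    """Ladder rule from week 2 on, driven by achieved days in the past week."""
    if perf.goal != prev.goal:
        raise ValidationError(
            f"performance refers to goal {perf.goal}, but previous state holds {prev.goal}"
        )
    if perf.days_achieved >= config.raise_threshold_days:
        proposal = prev.goal + config.increment
    elif perf.days_achieved >= config.hold_min_days:
        proposal = prev.goal
    else:
        proposal = prev.goal - config.increment
    return config.clamp(proposal)


def assess_confidence(confidence: float, config: GoalConfig = GoalConfig()) -> Verdict:
    """Classify reported confidence against the appropriate band (inclusive)."""
    if not (0 <= confidence <= 100):
        raise ValidationError(f"confidence must be in [0, 100], got {confidence}")
    if confidence < config.confidence_low:
        return Verdict.TOO_LOW
    if confidence > config.confidence_high:
        return Verdict.TOO_HIGH
    return Verdict.APPROPRIATE


def adjust_goal(goal: int, verdict: Verdict, config: GoalConfig = GoalConfig()) -> int:
    """Move the proposed goal one increment toward the appropriate band.

    Confidence above the band means the goal is too easy, so the goal is
    raised; below the band it is lowered.  Clamped to [floor, max_goal].
    """
    if verdict is Verdict.TOO_HIGH:
        return config.clamp(goal + config.increment)
    if verdict is Verdict.TOO_LOW:
        return config.clamp(goal - config.increment)
    return config.clamp(goal)


def finalize_goal(
    proposal: int,
    user_override: int | None,
    config: GoalConfig = GoalConfig(),
    week_index: int = 1,
    *,
    adjusted: bool = False,
    confidence: float | None = None,
    days_achieved_prev_week: int | None = None,
) -> GoalState:
    """Record the goal for the week: the user's self-set value if given
    (capped at ``max_goal``, like the app's input field), else the proposal."""
    if user_override is not None:
        if user_override > config.max_goal:
            raise ValidationError(
                f"self-set goal {user_override} exceeds the {config.max_goal} steps/day cap"
            )
        goal = config.clamp(user_override)
        source = GoalSource.SELF_SET
    else:
        goal = config.clamp(proposal)
        source = GoalSource.ADJUSTED if adjusted else GoalSource.SUGGESTED
    return GoalState(
        week_index=week_index,
        goal=goal,
        source=source,
        confidence=confidence,
        days_achieved_prev_week=days_achieved_prev_week,
    )


def negotiate_goal(
    suggestion: int,
    confidence_of: Callable[[int], float],
    config: GoalConfig = GoalConfig(),
) -> tuple[int, float, Verdict, list[dict]]:
    """Run the adjust-reassess loop for one weekly session.

    ``confidence_of(goal)`` reports the user's confidence for a candidate
    goal.  At most ``config.max_adjust_rounds`` adjustments are made; after
    that the last proposal stands regardless of verdict (termination
    guarantee).  Returns (final proposal, last confidence, last verdict, log).
    """
    goal = config.clamp(suggestion)
    log: list[dict] = []
    confidence = float(confidence_of(goal))
    verdict = assess_confidence(confidence, config)
    log.append({"goal": goal, "confidence": confidence, "verdict": verdict.value})
    rounds = 0
    while verdict is not Verdict.APPROPRIATE and rounds < config.max_adjust_rounds:
        new_goal = adjust_goal(goal, verdict, config)
        rounds += 1
        if new_goal == goal:  # pinned at floor or cap; adjusting again is futile
            break
        goal = new_goal
        confidence = float(confidence_of(goal))
        verdict = assess_confidence(confidence, config)
        log.append({"goal": goal, "confidence": confidence, "verdict": verdict.value})
    return goal, confidence, verdict, log


def load_goal_config(path) -> GoalConfig:
    """Load :class:`GoalConfig` fields from a JSON file (missing fields default)."""
    with open(path) as fh:
        data = json.load(fh)
    known = set(asdict(GoalConfig()).keys())
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown goal-config field(s) {sorted(unknown)}")
    return GoalConfig(**data)
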