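"""Weekly adherence scoring against a walking/exercise prescription.

Two definitions are computed per program (walking, exercise) over
Monday-anchored weeks:

* **program adherence** — days in the week on which the daily minute target
  was reached, divided by the prescribed days-per-week frequency. Unplanned
  days that reach the target count, so the ratio may exceed 1; it moves in
  steps of 1/frequency.
* **volume adherence** — total program minutes in the week divided by the
  weekly minute volume (daily target x days per week, e.g. 30 x 5 = 150 min
  of walking). Continuous and uncapped.

Per-day target states mirror what the participant-facing progress display
showed: a check mark on a planned day whose target was met, an opaque check
mark on an unplanned day whose target was met, and nothing otherwise —
exceeding the daily target earns no further reward.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal, Sequence

import pandas as pd

from .minutes import DailyMinutes
from .physiology import HrZone, hrr_zone

__all__ = [
    "Program",
    "Mark",
    "Prescription",
    "DayState",
    "AdherenceSummary",
    "UndefinedAdherenceError",
    "day_states",
    "program_adherence",
    "volume_adherence",
    "summarize_weeks",
    "summaries_to_frame",
]

Program = Literal["walking", "exercise"]

#: weekdays as Monday=0 .. Sunday=6, matching ``datetime.date.weekday``
WEEKDAYS = tuple(range(7))

#: guideline-style default plans: walking on the five weekdays, exercise Mon/Wed/Fri
DEFAULT_WALK_DAYS = frozenset({0, 1, 2, 3, 4})
DEFAULT_EXERCISE_DAYS = frozenset({0, 2, 4})


class UndefinedAdherenceError(ValueError):
    """Raised when a zero target frequency or volume makes adherence undefined."""


class Mark(str, Enum):
    """Per-day display state for one program."""

    NONE = "none"
    CHECK = "check"                # planned day, target met
    OPAQUE_CHECK = "opaque_check"  # unplanned day, target met


def _default_zone() -> HrZone:
    # 50-80% HRR for the cohort-mean physiology (age 73.8, HRrest 73)
    return hrr_zone(73.0, 211.0 - 0.8 * 73.8)


@dataclass(frozen=True)
class Prescription:
    """Weekly walking and exercise targets plus the exercise heart-rate zone.

    Defaults encode the guideline-derived program: 30 min/day of walking on
    five days per week and 25 min/day of exercise at 50-80% HRR on three
    days per week. ``walking_only`` drops the exercise program entirely
    (e.g. a participant contraindicated for higher-intensity work).
    """

    walk_target_min_per_day: float = 30.0
    walk_target_days_per_week: int = 5
    exercise_target_min_per_day: float = 25.0
    exercise_target_days_per_week: int = 3
    zone: HrZone = field(default_factory=_default_zone)
    planned_walk_days: frozenset[int] = DEFAULT_WALK_DAYS
    planned_exercise_days: frozenset[int] = DEFAULT_EXERCISE_DAYS
    walking_only: bool = False

    def __post_init__(self) -> None:
        if self.walk_target_min_per_day < 0 or self.exercise_target_min_per_day < 0:
            raise ValueError("daily minute targets must be non-negative")
        if not set(self.planned_walk_days) <= set(WEEKDAYS):
            raise ValueError("planned_walk_days must be weekday indices 0-6")
        if not set(self.planned_exercise_days) <= set(WEEKDAYS):
            raise ValueError("planned_exercise_days must be weekday indices 0-6")
        if len(self.planned_walk_days) != self.walk_target_days_per_week:
            raise ValueError(
                "planned_walk_days size must equal walk_target_days_per_week"
            )
        if not self.walking_only and (
            len(self.planned_exercise_days) != self.exercise_target_days_per_week
        ):
            raise ValueError(
                "planned_exercise_days size must equal exercise_target_days_per_week"
            )

    def daily_target(self, program: Program) -> float:
        return (
            self.walk_target_min_per_day
            if program == "walking"
            else self.exercise_target_min_per_day
        )

    def target_frequency(self, program: Program) -> int:
        return (
            self.walk_target_days_per_week
            if program == "walking"
            else self.exercise_target_days_per_week
        )

    def weekly_volume(self, program: Program) -> float:
        """Weekly minute denominator, e.g. 30 x 5 = 150 walking minutes."""
        return self.daily_target(program) * self.target_frequency(program)

    def planned_days(self, program: Program) -> frozenset[int]:
        return (
            frozenset(self.planned_walk_days)
            if program == "walking"
            else frozenset(self.planned_exercise_days)
        )

    def programs(self) -> tuple[Program, ...]:
        return ("walking",) if self.walking_only else ("walking", "exercise")


@dataclass(frozen=True)
class DayState:
    """Per-day, per-program progress as the display would render it."""

    date: dt.date
    program: Program
    planned: bool
    achieved_fraction: float    # minutes / daily target, uncapped
    target_met: bool
    mark: Mark


@dataclass(frozen=True)
class AdherenceSummary:
    """Both adherence definitions for both programs over one calendar week.

    Exercise fields are ``None`` for walking-only prescriptions. ``complete``
    is False for partial first/last weeks of a recording.
    """

    week_start: dt.date
    walk_program_adherence: float
    walk_volume_adherence: float
    exercise_program_adherence: float | None
    exercise_volume_adherence: float | None
    days_meeting_walk_target: int
    days_meeting_exercise_target: int | None
    complete: bool = True
    participant_id: str = ""


def _week_map(week: Sequence[DailyMinutes]) -> tuple[dt.date, dict[dt.date, DailyMinutes]]:
    if not week:
        raise ValueError("week must contain at least one DailyMinutes record")
    start = min(d.date for d in week)
    if start.weekday() != 0:
        raise ValueError(f"week must start on a Monday, got {start} ({start.strftime('%A')})")
    end = start + dt.timedelta(days=6)
    by_date: dict[dt.date, DailyMinutes] = {}
    for d in week:
        if not (start <= d.date <= end):
            raise ValueError(f"day {d.date} outside week starting {start}")
        if d.date in by_date:
            raise ValueError(f"duplicate DailyMinutes for {d.date}")
        by_date[d.date] = d
    return start, by_date


def _minutes(day: DailyMinutes | None, program: Program) -> float:
    if day is None:
        return 0.0
    return day.walking_minutes if program == "walking" else day.exercise_minutes


def day_states(week: Sequence[DailyMinutes], rx: Prescription) -> list[DayState]:
    """Per-day target states for a Monday-anchored week (missing days = zero)."""
    start, by_date = _week_map(week)
    states: list[DayState] = []
    for offset in range(7):
        date = start + dt.timedelta(days=offset)
        day = by_date.get(date)
        for program in rx.programs():
            target = rx.daily_target(program)
            minutes = _minutes(day, program)
            fraction = minutes / target if target > 0 else 0.0
            met = target > 0 and minutes >= target
            planned = date.weekday() in rx.planned_days(program)
            if met:
                mark = Mark.CHECK if planned else Mark.OPAQUE_CHECK
            else:
                mark = Mark.NONE
            states.append(
                DayState(
                    date=date,
                    program=program,
                    planned=planned,
                    achieved_fraction=fraction,
                    target_met=met,
                    mark=mark,
                )
            )
    return states


def program_adherence(
    week: Sequence[DailyMinutes], rx: Prescription, program: Program
) -> float:
    """Days reaching the daily target (planned or not) / target frequency."""
    freq = rx.target_frequency(program)
    if freq <= 0:
        raise UndefinedAdherenceError(f"{program} target frequency is zero")
    target = rx.daily_target(program)
    _, by_date = _week_map(week)
    qualifying = sum(1 for d in by_date.values() if _minutes(d, program) >= target and target > 0)
    return qualifying / freq


def volume_adherence(
    week: Sequence[DailyMinutes], rx: Prescription, program: Program
) -> float:
    """Total weekly program minutes / prescribed weekly minute volume."""
    volume = rx.weekly_volume(program)
    if volume <= 0:
        raise UndefinedAdherenceError(f"{program} weekly target volume is zero")
    _, by_date = _week_map(week)
    return sum(_minutes(d, program) for d in by_date.values()) / volume


def summarize_weeks(
    daily: Iterable[DailyMinutes],
    rx: Prescription,
    participant_id: str = "",
) -> list[AdherenceSummary]:
    """One AdherenceSummary per Monday-anchored calendar week of the recording.

    Weeks without any day of data between the first and last observed week
    are still emitted (all-zero adherence) so the study calendar stays
    contiguous; partial boundary weeks carry ``complete=False``.
    """
    daily = sorted(daily, key=lambda d: d.date)
    if not daily:
        return []
    first, last = daily[0].date, daily[-1].date
    first_monday = first - dt.timedelta(days=first.weekday())
    last_monday = last - dt.timedelta(days=last.weekday())
    by_date = {d.date: d for d in daily}

    summaries: list[AdherenceSummary] = []
    monday = first_monday
    while monday <= last_monday:
        days = [
            by_date[monday + dt.timedelta(days=k)]
            for k in range(7)
            if monday + dt.timedelta(days=k) in by_date
        ]
        week = days or [DailyMinutes(date=monday, walking_minutes=0.0, exercise_minutes=0.0)]
        complete = all(monday + dt.timedelta(days=k) in by_date for k in range(7))
        walk_target = rx.daily_target("walking")
        summary = AdherenceSummary(
            week_start=monday,
            walk_program_adherence=program_adherence(week, rx, "walking"),
            walk_volume_adherence=volume_adherence(week, rx, "walking"),
            exercise_program_adherence=(
                None if rx.walking_only else program_adherence(week, rx, "exercise")
            ),
            exercise_volume_adherence=(
                None if rx.walking_only else volume_adherence(week, rx, "exercise")
            ),
            days_meeting_walk_target=sum(
                1 for d in week if walk_target > 0 and d.walking_minutes >= walk_target
            ),
            days_meeting_exercise_target=(
                None
                if rx.walking_only
                else sum(
                    1
                    for d in week
                    if d.exercise_minutes >= rx.daily_target("exercise")
                )
            ),
            complete=complete,
            participant_id=participant_id,
        )
        summaries.append(summary)
        monday += dt.timedelta(days=7)
    return summaries


_METRICS = (
    ("walking program adherence", "walk_program_adherence"),
    ("walking volume adherence", "walk_volume_adherence"),
    ("exercise program adherence", "exercise_program_adherence"),
    ("exercise volume adherence", "exercise_volume_adherence"),
)


def summaries_to_frame(
    summaries: Iterable[AdherenceSummary],
    week_labels: dict[dt.date, str] | None = None,
) -> pd.DataFrame:
    """Tidy long table (participant, week, metric, value_percent).

    Fractions are rendered as percentages at this interface; missing
    exercise metrics (walking-only prescriptions) are omitted.
    """
    rows = []
    for s in summaries:
        label = (week_labels or {}).get(s.week_start, s.week_start.isoformat())
        for metric, attr in _METRICS:
            value = getattr(s, attr)
            if value is None:
                continue
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "week": label,
                    "week_start": s.week_start.isoformat(),
                    "metric": metric,
                    "value_percent": 100.0 * value,
                    "complete_week": s.complete,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "week",
            "week_start",
            "metric",
            "value_percent",
            "complete_week",
        ],
    )
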