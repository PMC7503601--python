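"""Minute-stream derivation: raw wrist-monitor streams to daily activity tallies.

The wrist monitor reports, per calendar minute, the number of seconds spent
walking (from its validated accelerometer classifier) and the minute-mean
optical heart rate. Two daily tallies are derived:

* **walking minutes** — walking seconds accumulated over *bouts*, where a
  bout is a maximal run of consecutive minutes with any walking and bouts
  whose total walking time falls below a duration threshold (default 110 s,
  i.e. two minutes minus a 10 s tolerance) are discarded entirely;
* **exercise minutes** — a plain count of minutes whose mean heart rate
  falls inside the prescribed target zone, with **no** minimum-bout rule
  (isolated in-zone minutes count) and minutes with missing HR never
  counting.

Streams are exchanged as CSV with columns
``participant_id,date,minute,walking_seconds,mean_hr`` (minute-of-day
0-1439; missing HR as an empty field).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .physiology import HrZone

__all__ = [
    "MinuteRecord",
    "DayStream",
    "Bout",
    "DailyMinutes",
    "StreamStructureError",
    "DEFAULT_MIN_BOUT_SECONDS",
    "detect_walking_bouts",
    "count_exercise_minutes",
    "summarize_day",
    "read_streams_csv",
    "write_streams_csv",
    "streams_from_frame",
]

#: two minutes minus the 10 s tolerance; bouts strictly shorter are dropped
DEFAULT_MIN_BOUT_SECONDS = 110.0

STREAM_COLUMNS = ["participant_id", "date", "minute", "walking_seconds", "mean_hr"]


class StreamStructureError(ValueError):
    """Raised for non-chronological or structurally inconsistent streams."""


@dataclass(frozen=True)
class MinuteRecord:
    """One calendar minute of monitor output."""

    timestamp: dt.datetime          # truncated to the minute
    walking_seconds: float          # in [0, 60]
    mean_hr: float | None = None    # beats/min, None when the optical signal dropped

    def __post_init__(self) -> None:
        if not (0.0 <= self.walking_seconds <= 60.0):
            raise ValueError(
                f"walking_seconds must lie in [0, 60], got {self.walking_seconds}"
            )
        if self.mean_hr is not None:
            if not math.isfinite(self.mean_hr) or not (25.0 <= self.mean_hr <= 230.0):
                raise ValueError(f"mean_hr {self.mean_hr} outside plausible [25, 230]")


@dataclass(frozen=True)
class DayStream:
    """Ordered minute records for one participant-day (wear time only)."""

    participant_id: str
    date: dt.date
    records: tuple[MinuteRecord, ...]

    def __post_init__(self) -> None:
        prev = None
        for rec in self.records:
            if rec.timestamp.date() != self.date:
                raise StreamStructureError(
                    f"record at {rec.timestamp} does not belong to {self.date}"
                )
            if prev is not None and rec.timestamp <= prev:
                raise StreamStructureError(
                    f"timestamps not strictly increasing at {rec.timestamp}"
                )
            prev = rec.timestamp

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Bout:
    """A counted activity interval (inclusive minute bounds)."""

    start: dt.datetime
    end: dt.datetime
    kind: Literal["walking", "exercise"]
    total_seconds: float


@dataclass(frozen=True)
class DailyMinutes:
    """Daily walking and exercise tallies plus the counted bout inventory."""

    date: dt.date
    walking_minutes: float
    exercise_minutes: float
    bouts: tuple[Bout, ...] = field(default_factory=tuple)
    participant_id: str = ""


def detect_walking_bouts(
    stream: DayStream,
    min_bout_seconds: float = DEFAULT_MIN_BOUT_SECONDS,
    max_gap_minutes: int = 0,
) -> list[Bout]:
    """Find counted walking bouts in one day's stream.

    A bout is a maximal run of consecutive calendar minutes with
    ``walking_seconds > 0``; up to ``max_gap_minutes`` consecutive
    zero-walking minutes are tolerated inside a bout (default 0: any pause
    ends the bout). Bouts whose summed walking seconds fall below
    ``min_bout_seconds`` are discarded and contribute nothing to the day's
    walking minutes.
    """
    if min_bout_seconds <= 0:
        raise ValueError("min_bout_seconds must be positive")
    if max_gap_minutes < 0:
        raise ValueError("max_gap_minutes must be non-negative")

    bouts: list[Bout] = []
    run: list[MinuteRecord] = []   # current bout's walking minutes
    gap = 0                        # consecutive non-walking minutes seen inside the run
    prev_ts: dt.datetime | None = None

    def flush() -> None:
        if not run:
            return
        total = sum(r.walking_seconds for r in run)
        if total >= min_bout_seconds:
            bouts.append(
                Bout(
                    start=run[0].timestamp,
                    end=run[-1].timestamp,
                    kind="walking",
                    total_seconds=total,
                )
            )
        run.clear()

    for rec in stream.records:
        contiguous = (
            prev_ts is not None
            and (rec.timestamp - prev_ts) == dt.timedelta(minutes=1)
        )
        if rec.walking_seconds > 0:
            if run and not contiguous:
                # wear-time gap in the recording itself always breaks the bout
                flush()
                gap = 0
            run.append(rec)
            gap = 0
        else:
            if run:
                gap += 1
                if gap > max_gap_minutes or not contiguous:
                    flush()
                    gap = 0
        prev_ts = rec.timestamp
    flush()
    return bouts


def count_exercise_minutes(stream: DayStream, zone: HrZone) -> float:
    """Count minutes with mean HR inside the closed target zone.

    No minimum-bout filter applies (an isolated in-zone minute counts);
    minutes with missing HR never count.
    """
    return float(
        sum(
            1
            for rec in stream.records
            if rec.mean_hr is not None and zone.contains(rec.mean_hr)
        )
    )


def _exercise_bouts(stream: DayStream, zone: HrZone) -> list[Bout]:
    # inventory only; exercise counting itself ignores bout structure
    bouts: list[Bout] = []
    run: list[MinuteRecord] = []
    prev_ts = None
    for rec in stream.records:
        in_zone = rec.mean_hr is not None and zone.contains(rec.mean_hr)
        contiguous = (
            prev_ts is not None and (rec.timestamp - prev_ts) == dt.timedelta(minutes=1)
        )
        if in_zone and (not run or contiguous):
            run.append(rec)
        else:
            if run:
                bouts.append(
                    Bout(run[0].timestamp, run[-1].timestamp, "exercise", 60.0 * len(run))
                )
                run.clear()
            if in_zone:
                run.append(rec)
        prev_ts = rec.timestamp
    if run:
        bouts.append(Bout(run[0].timestamp, run[-1].timestamp, "exercise", 60.0 * len(run)))
    return bouts


def summarize_day(
    stream: DayStream,
    zone: HrZone,
    min_bout_seconds: float = DEFAULT_MIN_BOUT_SECONDS,
    max_gap_minutes: int = 0,
) -> DailyMinutes:
    """Apply both counting rules to one participant-day."""
    walking_bouts = detect_walking_bouts(stream, min_bout_seconds, max_gap_minutes)
    walking_minutes = sum(b.total_seconds for b in walking_bouts) / 60.0
    exercise_minutes = count_exercise_minutes(stream, zone)
    return DailyMinutes(
        date=stream.date,
        walking_minutes=walking_minutes,
        exercise_minutes=exercise_minutes,
        bouts=tuple(walking_bouts) + tuple(_exercise_bouts(stream, zone)),
        participant_id=stream.participant_id,
    )


# ---------------------------------------------------------------------------
# CSV stream dialect


def streams_from_frame(frame: pd.DataFrame) -> list[DayStream]:
    """Build DayStreams from a tidy minute table (one row per worn minute)."""
    missing = set(STREAM_COLUMNS) - set(frame.columns)
    if missing:
        raise StreamStructureError(f"stream table missing columns {sorted(missing)}")
    streams: list[DayStream] = []
    for (pid, date), grp in frame.groupby(["participant_id", "date"], sort=True):
        date = pd.Timestamp(date).date()
        grp = grp.sort_values("minute")
        records = tuple(
            MinuteRecord(
                timestamp=dt.datetime.combine(date, dt.time()) + dt.timedelta(minutes=int(m)),
                walking_seconds=float(w),
                mean_hr=None if pd.isna(h) else float(h),
            )
            for m, w, h in zip(grp["minute"], grp["walking_seconds"], grp["mean_hr"])
        )
        streams.append(DayStream(participant_id=str(pid), date=date, records=records))
    return streams


def read_streams_csv(path: str | Path) -> list[DayStream]:
    """Read the minute-stream CSV dialect (empty mean_hr field = missing)."""
    frame = pd.read_csv(path, dtype={"participant_id": str})
    return streams_from_frame(frame)


def write_streams_csv(streams: Iterable[DayStream], path: str | Path) -> None:
    rows = []
    for s in streams:
        for rec in s.records:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "date": s.date.isoformat(),
                    "minute": rec.timestamp.hour * 60 + rec.timestamp.minute,
                    "walking_seconds": rec.walking_seconds,
                    "mean_hr": rec.mean_hr,
                }
            )
    pd.DataFrame(rows, columns=STREAM_COLUMNS).to_csv(path, index=False)
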