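"""Shared fixtures: hand-built minute streams and prescriptions."""

from __future__ import annotations

import datetime as dt

import pytest

from wearadhere.adherence import Prescription
from wearadhere.minutes import DayStream, MinuteRecord
from wearadhere.physiology import hrr_zone

MONDAY = dt.date(2020, 1, 6)


def build_stream(
    walking_seconds,
    mean_hr=None,
    date: dt.date = MONDAY,
    start_minute: int = 8 * 60,
    participant_id: str = "P01",
) -> DayStream:
    """Build a DayStream from parallel per-minute lists.

    ``mean_hr`` may be None (all missing), a scalar, or a list with None
    entries for missing minutes.
    """
    n = len(walking_seconds)
    if mean_hr is None:
        hr = [None] * n
    elif isinstance(mean_hr, (int, float)):
        hr = [float(mean_hr)] * n
    else:
        hr = list(mean_hr)
    midnight = dt.datetime.combine(date, dt.time())
    records = tuple(
        MinuteRecord(
            timestamp=midnight + dt.timedelta(minutes=start_minute + i),
            walking_seconds=float(w),
            mean_hr=None if h is None else float(h),
        )
        for i, (w, h) in enumerate(zip(walking_seconds, hr))
    )
    return DayStream(participant_id=participant_id, date=date, records=records)


@pytest.fixture
def rx() -> Prescription:
    """The guideline prescription: 30x5 walking, 25x3 exercise at 50-80% HRR."""
    return Prescription()


@pytest.fixture
def zone():
    """A simple round-number Karvonen zone: rest 60, max 160 -> (110, 140)."""
    return hrr_zone(60.0, 160.0)
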