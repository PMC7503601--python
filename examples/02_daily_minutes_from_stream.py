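"""From a raw minute stream to daily walking and exercise minutes.

Builds one morning of watch output by hand: a 25-minute walk, a 90-second
shuffle to the mailbox (below the bout threshold), and a 20-minute
brisk-walking block that drives the heart rate into the exercise zone.
"""

import datetime as dt

from wearadhere import DayStream, MinuteRecord, hrr_zone, summarize_day

zone = hrr_zone(60.0, 160.0)  # (110, 140) bpm
day = dt.date(2020, 1, 6)
midnight = dt.datetime.combine(day, dt.time())

records = []
minute = 8 * 60  # 08:00


def add(walk_seconds, hr, n):
    global minute
    for _ in range(n):
        records.append(
            MinuteRecord(midnight + dt.timedelta(minutes=minute), walk_seconds, hr)
        )
        minute += 1


add(60, 95, 25)    # 25-min walk, HR below the zone
add(0, 75, 30)     # rest
add(60, 80, 1)     # 90-second errand: too short to count
add(30, 80, 1)
add(0, 75, 30)     # rest
add(0, 125, 20)    # brisk effort in the zone (not flagged as walking)

stream = DayStream(participant_id="P01", date=day, records=tuple(records))
result = summarize_day(stream, zone)

print(f"Walking minutes counted: {result.walking_minutes:.1f}")
print(f"Exercise minutes counted: {result.exercise_minutes:.0f}")
for b in result.bouts:
    print(f"  {b.kind:8s} {b.start.time()}–{b.end.time()}  {b.total_seconds:.0f} s")
print()
print("The 90-second errand is absent: walking bouts shorter than 110 s")
print("(two minutes minus a 10 s tolerance) are discarded. Exercise minutes")
print("have no minimum bout — every in-zone minute counts.")
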