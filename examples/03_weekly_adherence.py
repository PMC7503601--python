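"""Scoring one week against the walking/exercise prescription.

The default program asks for 30 min of walking on five days (150 min/week)
and 25 min of in-zone exercise on three days (75 min/week). This
participant walked on four planned days plus Saturday, and exercised twice.
"""

import datetime as dt

from wearadhere import DailyMinutes, Mark, Prescription, day_states, summarize_weeks

rx = Prescription()
monday = dt.date(2020, 1, 6)
walk = [35, 30, 0, 31, 30, 40, 0]      # Mon..Sun walking minutes
exercise = [25, 0, 26, 0, 0, 0, 0]     # exercise (in-zone) minutes

week = [
    DailyMinutes(date=monday + dt.timedelta(days=i),
                 walking_minutes=float(w), exercise_minutes=float(e))
    for i, (w, e) in enumerate(zip(walk, exercise))
]

(summary,) = summarize_weeks(week, rx)
print(f"Walking  program adherence: {100 * summary.walk_program_adherence:.0f}%  "
      f"({summary.days_meeting_walk_target} qualifying days / 5 planned)")
print(f"Walking  volume  adherence: {100 * summary.walk_volume_adherence:.0f}%  "
      f"({sum(walk):.0f} of 150 min)")
print(f"Exercise program adherence: {100 * summary.exercise_program_adherence:.0f}%")
print(f"Exercise volume  adherence: {100 * summary.exercise_volume_adherence:.0f}%")
print()
for state in day_states(week, rx):
    if state.program == "walking" and state.mark is not Mark.NONE:
        kind = "planned" if state.planned else "unplanned"
        print(f"  {state.date} walking target met ({kind}) -> {state.mark.value}")
print()
print("Saturday's walk earns an opaque check (unplanned day acknowledged) and")
print("counts toward program adherence, which may therefore exceed 100%.")
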