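"""Monitor a respondent's recovery over four quarterly sittings.

Simulates a history of four GHQ+CBI sittings three months apart with
falling burnout targets, then prints the recent-diagnosis chart series,
the per-dimension deltas of the last two sittings, the status message,
and the next retest due date.
"""

from datetime import date

from burnoutkit import (
    RespondentProfile,
    dimension_deltas,
    next_due,
    recent_diagnoses,
    simulate_history,
    status_message,
)

profiles = [
    RespondentProfile(ghq_negativity=neg, cbi_target={"personal": t, "work": t, "client": t})
    for t, neg in [(90, 0.6), (60, 0.3), (40, 0.1), (10, 0.0)]
]
history = simulate_history(profiles, start=date(2022, 1, 15), interval_months=3, seed=42)

print("Last four sittings (oldest first):")
for point in recent_diagnoses(history, n=4):
    print(f"  {point.timestamp.date()}  risk={point.overall_risk.value:<8}  "
          f"category={point.category.value}")

print("\nChange since the previous sitting (lower burnout is better):")
for delta in dimension_deltas(history).deltas:
    print(f"  {delta.dimension.value:<8} {delta.previous:6.2f} -> {delta.current:6.2f}  "
          f"{delta.trend.value}")

last = history.records[-1]
print(f"\nStatus message : {status_message(last).value}")
print(f"Next retest due: {next_due(last)}")
# The series walks down the risk ladder as the targets fall; the final
# sitting has low scores everywhere and no distress, and the respondent
# is asked back three calendar months after the last timestamp.
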