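"""Derive a regimen course from a small dispensing history.

One subject starts on moderate-intensity atorvastatin, switches statin at
the same intensity (not a modification), then moves to a high-intensity
dose (an escalation), with a refill gap that costs adherence.
"""

import statin_pgx as sp

events = [
    sp.DispensingEvent("pt1", 0, "atorvastatin", 20, 30),
    sp.DispensingEvent("pt1", 30, "rosuvastatin", 10, 30),   # same intensity
    sp.DispensingEvent("pt1", 150, "rosuvastatin", 20, 30),  # high intensity
    sp.DispensingEvent("pt1", 180, "rosuvastatin", 20, 30),
]

course = sp.derive_course(events, followup_days=365)
print("trajectory:")
for day, drug, dose, intensity in course.trajectory:
    print(f"  day {day:>3}: {drug} {dose:g} mg  ->  {intensity}")
print(f"modification        : {course.modification}")
print(f"time to first change: {course.time_to_first_change} days")
print(f"switch count        : {course.switch_count}")
print(f"MPR                 : {course.mpr:.3f}  (adherent: {course.adherent})")

print()
print("The day-30 statin switch preserves moderate intensity, so the course")
print("is classified by the day-150 moderate->high transition (escalation).")
print("Only 120 of 365 days were covered, hence MPR 0.329: non-adherent.")
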