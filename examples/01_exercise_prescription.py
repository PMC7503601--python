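"""Personal exercise prescription: maximal HR, Karvonen zone, 6-MWT fitness.

A 74-year-old with a resting HR of 73 bpm walked 508 m in a six-minute walk
test; seated-rest oxygen uptake was 300 mL/min.
"""

from wearadhere import SixMwtInputs, hrr_zone, kervio_crf, tanaka_hrmax

age, hr_rest = 74.0, 73.0

hr_max = tanaka_hrmax(age)
zone = hrr_zone(hr_rest, hr_max)  # defaults: 50-80% of heart-rate reserve
crf = kervio_crf(
    SixMwtInputs(age=age, body_mass=80.0, height=170.0, distance=508.0,
                 vo2_rest=300.0, hr_test=hr_rest)
)

print(f"Age-predicted HRmax (sedentary): {hr_max:.1f} bpm")
print(f"Exercise target zone (50-80% HRR): {zone.lower:.1f}-{zone.upper:.1f} bpm")
print(f"Estimated VO2max: {crf.vo2max_abs:.1f} mL/min "
      f"({crf.vo2max_rel:.1f} mL/kg/min)")
print()
print("Exercise minutes are those whose minute-mean HR falls inside the zone;")
print("the VO2max estimate is the linear 6-MWT regression, typical of a")
print("moderately fit older adult at ~25 mL/kg/min.")
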