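"""Personalized, context-adjusted normal ranges and state labeling.

The same heart rate can be normal during a climb and alarming at rest:
thresholds adapt to activity, temperature, age, gender and altitude.
"""

from vitalfield import SubjectProfile, EnvContext, compute_thresholds
from vitalfield.labeling import label_state

resting = EnvContext(altitude=0.0, temperature=20.0, activity_level=0.0)
climbing = EnvContext(altitude=3000.0, temperature=35.0, activity_level=0.8)
soldier = SubjectProfile("S001", age=28, gender="male")

for name, ctx in (("at rest, sea level", resting), ("climbing at 3000 m, 35 C", climbing)):
    t = compute_thresholds(soldier, ctx)
    print(f"{name}:")
    print(f"  HR/pulse normal range : [{t.hr_lo:.1f}, {t.hr_hi:.1f}] bpm")
    print(f"  RESP normal range     : [{t.resp_lo:.1f}, {t.resp_hi:.1f}] breaths/min")
    print(f"  SpO2 floor            : {t.spo2_lo:.1f} %")

hr, spo2, resp, pulse = 128.0, 93.5, 24.0, 126.0
for name, ctx in (("at rest", resting), ("climbing", climbing)):
    state = label_state(hr, spo2, resp, pulse, compute_thresholds(soldier, ctx))
    print(f"HR {hr:.0f} / SpO2 {spo2:.1f} / RESP {resp:.0f} / pulse {pulse:.0f} "
          f"while {name}: {state}")
print("The identical vitals flip from abnormal to normal once context is accounted for.")
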