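"""Run the three deterioration-alert algorithms on one patient.

A 120-day series carries one injected decompensation (weight +3 kg,
impedance -5 ohm over 14 days, hospitalization at day 80).  The weight rule
of thumb fires on short-term jumps, the MACD trend detector on the sustained
weight drift, and the CUSUM on the standardized impedance decline.
"""

from htmsim import (
    CohortConfig,
    DecompensationEvent,
    cusum_impedance_alerts,
    generate_vitals,
    macd_weight_alerts,
    rot_weight_alerts,
)
from htmsim.cohort import PatientProfile

profile = PatientProfile(
    patient_id="DEMO", sex="male", age=63, bmi=29, lvef=31, nyha="III",
    aetiology="ischaemic", comorbidities=("diabetes",),
    baseline_weight=85.0, baseline_impedance=30.0,
)
event = DecompensationEvent(
    patient_id="DEMO", onset_day=66, hospitalization_day=80,
    weight_gain_total=3.0, impedance_drop_total=5.0, ramp_days=14,
)
config = CohortConfig(duration_days=120, compliance=0.95)
vitals = generate_vitals(profile, [event], config, seed=7)

for algo in (rot_weight_alerts, macd_weight_alerts, cusum_impedance_alerts):
    res = algo(vitals)
    days = res.alert_days.tolist()
    in_window = [d for d in days if 80 - 28 <= d < 80]
    print(f"{res.algorithm:16s}: {len(days):3d} alert days {days[:8]}"
          f"{' ...' if len(days) > 8 else ''}")
    print(f"{'':16s}  {len(in_window)} fall in the 28 days before "
          f"hospitalization (day 80) -> event {'detected' if in_window else 'missed'}")
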