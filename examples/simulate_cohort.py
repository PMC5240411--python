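"""Generate a small synthetic heart-failure telemonitoring cohort.

Each patient gets a demographic profile, daily vitals (weight, blood
pressure, heart rate, trans-thoracic impedance) with missing days, a symptom
diary, and possibly decompensation events that ramp weight up and impedance
down before a hospitalization.
"""

import numpy as np

from htmsim import CohortConfig, simulate_cohort

config = CohortConfig(n_patients=20, duration_days=300, seed=42)
data = simulate_cohort(config)

ages = [p.age for p in data.profiles]
males = sum(p.sex == "male" for p in data.profiles)
print(f"cohort: {len(data.profiles)} patients, {males} male")
print(f"age mean {np.mean(ages):.1f} sd {np.std(ages):.1f} years")
print(f"decompensation events: {len(data.events)} "
      f"({len(data.events) / len(data.profiles):.2f} per patient over 300 days)")

ev = data.events[0]
v = data.vitals[ev.patient_id]
pre = v.weight[max(0, ev.onset_day - 5):ev.onset_day]
peak = v.weight[ev.hospitalization_day]
print(f"\npatient {ev.patient_id}: hospitalized day {ev.hospitalization_day}")
print(f"  weight before onset ~{np.nanmean(pre):.1f} kg, "
      f"at hospitalization {peak:.1f} kg "
      f"(the event injects +{ev.weight_gain_total:.0f} kg over {ev.ramp_days} days)")
obs = int(v.observed_mask().sum())
print(f"  {obs}/{len(v.day)} days observed (compliance {config.compliance:.0%})")
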