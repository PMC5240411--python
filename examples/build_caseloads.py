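"""From alerts to review caseloads and a simulated-call symptom report.

Alert days become 28-day episodes ending on the alert; runs of consecutive
alerts are thinned to every third episode; episodes are labeled by whether
the patient decompensates within 28 days, split into caseloads, padded with
alert-free filler windows and given fictitious names.
"""

from htmsim import (
    CohortConfig,
    assemble_caseloads,
    build_episodes,
    build_filler_pool,
    label_all,
    make_call_report,
    prune_consecutive,
    rot_weight_alerts,
    simulate_cohort,
)

data = simulate_cohort(CohortConfig(n_patients=30, duration_days=300, seed=3))
alerts = {pid: rot_weight_alerts(v) for pid, v in data.vitals.items()}

episodes = []
for pid in sorted(alerts):
    episodes.extend(build_episodes(alerts[pid], data.vitals[pid]))
pruned = label_all(prune_consecutive(episodes), data.events)
print(f"{len(episodes)} raw alert episodes -> {len(pruned)} after pruning "
      f"consecutive-day duplicates")
n_dec = sum(e.decompensated for e in pruned)
print(f"{n_dec} episodes ({n_dec / len(pruned):.0%}) precede a decompensation "
      f"within 28 days")

filler = build_filler_pool(data.vitals, alerts)
caseloads = assemble_caseloads(pruned, filler, n_caseloads=15,
                               filler_fraction=0.5, seed=1, arm="demo")
cl = caseloads[0]
print(f"\ncaseload 1 of {len(caseloads)}: {len(cl.alert_episodes)} alerts + "
      f"{len(cl.filler_episodes)} filler patients")
first = cl.alert_episodes[0]
print(f"  top of list: '{first.display_name}' (alert day {first.end_day}, "
      f"decompensated={first.decompensated})")

report = make_call_report(data.diaries[first.patient_id], first.end_day)
print(f"\nsimulated call for day {report.day} "
      f"(mood reference over prior 2 weeks: {report.mood_ref:.1f}/5):")
for q, colors in report.color_codes.items():
    print(f"  {q:22s} {' '.join(c[0].upper() for c in colors)}   "
          "(W=none, Y=once, R=twice or more, M=missing; last 5 days)")
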