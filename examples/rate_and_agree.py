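"""Simulate a clinician panel and measure inter-rater agreement.

Eight raters review the alert episodes of a caseload set; each response is a
1-5 meaningfulness rating plus an action (no action / beginning / raised /
high concern).  Agreement on the binary action decision is summarized by raw
rater-pair agreement and Fleiss' kappa with a case-resampling bootstrap CI.
"""

from htmsim import (
    CohortConfig,
    assemble_caseloads,
    bootstrap_ci,
    build_episodes,
    build_filler_pool,
    collapse_to_action,
    fleiss_kappa,
    label_all,
    make_panel,
    prune_consecutive,
    raw_agreement,
    rot_weight_alerts,
    simulate_cohort,
    simulate_responses,
)

data = simulate_cohort(CohortConfig(n_patients=30, duration_days=300, seed=3))
alerts = {pid: rot_weight_alerts(v) for pid, v in data.vitals.items()}
episodes = []
for pid in sorted(alerts):
    episodes.extend(build_episodes(alerts[pid], data.vitals[pid]))
labeled = label_all(prune_consecutive(episodes), data.events)
caseloads = assemble_caseloads(labeled, build_filler_pool(data.vitals, alerts),
                               seed=1, arm="demo")

panel = make_panel(n_raters=8, policy_spread=0.3, seed=5)
responses = simulate_responses(panel, caseloads, seed=6, missing_rate=0.02)
print(f"{len(responses)} responses from {len(panel)} raters on "
      f"{len(labeled)} alert episodes")

matrix = collapse_to_action(responses, panel_size=8)
agree = raw_agreement(matrix)
kappa = bootstrap_ci(matrix, fleiss_kappa, n_boot=2000, seed=7)
print(f"complete cases (all 8 raters responded): {int(matrix.complete.sum())}"
      f" of {len(matrix.case_ids)}")
print(f"raw rater-pair agreement on action: {agree:.1%}")
print(f"Fleiss kappa (complete cases): {kappa.statistic:.3f} "
      f"(95% bootstrap CI {kappa.ci_low:.3f}-{kappa.ci_high:.3f})")
print("kappa ~0.3-0.5 = modest agreement beyond chance: clinicians often "
      "disagree on whether an alert needs action")
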