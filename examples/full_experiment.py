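"""The full simulated experiment: simple vs advanced alerting.

Arm A reviews weight rule-of-thumb alerts with 8 raters; arm P splits 4 + 4
raters over the weight-MACD and impedance-CUSUM sub-arms.  The run prints the
alert-burden, workload, agreement and detection-composition comparison.
"""

from htmsim import ExperimentConfig, run_experiment

result, manifest = run_experiment(ExperimentConfig(master_seed=1))
print(f"run {manifest.config_hash}: "
      f"{manifest.record_counts['patients']} patients, "
      f"{manifest.record_counts['events']} decompensation events\n")

for arm, a in result.arms.items():
    s = a.summary
    print(f"arm {arm} ({a.algorithm}): {len(a.episodes_raw)} alert episodes, "
          f"{len(a.episodes)} after pruning")
    print(f"   sensitivity to decompensation {a.sensitivity:.0%}; "
          f"review {s.total_minutes_mean:.0f} +/- {s.total_minutes_sd:.0f} min/rater "
          f"({s.per_alert_seconds_mean:.0f} s/alert)")
    print(f"   kappa {a.kappa_binary.statistic:.3f} "
          f"({a.kappa_binary.ci_low:.3f}-{a.kappa_binary.ci_high:.3f}); "
          f"concern rate on true decompensations {a.concern_rate_decomp:.0%}; "
          f"detection-weighted action rate {a.detection_weighted_action_rate:.0%}")

mean_a = sum(result.total_minutes_arm_a) / len(result.total_minutes_arm_a)
mean_p = sum(result.total_minutes_arm_p) / len(result.total_minutes_arm_p)
print(f"\ntotal review time: arm A {mean_a:.0f} min vs arm P {mean_p:.0f} min "
      f"(Mann-Whitney two-sided p = {result.mann_whitney_p:.4f})")
print(f"pooled arm P kappa {result.pooled_kappa.statistic:.3f} "
      f"({result.pooled_kappa.ci_low:.3f}-{result.pooled_kappa.ci_high:.3f})")
print("\nfewer but better-targeted alerts cut reviewer workload; agreement on "
      "what to do about an alert stays modest in every arm")
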