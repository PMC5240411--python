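# htmsim

Simulated home-telemonitoring (HTM) case management for chronic heart failure.

Daily remote monitoring of weight, blood pressure, heart rate and
trans-thoracic impedance (TTI) can catch fluid accumulation before a heart
failure patient decompensates — but only if the alert algorithm on top of the
data stream produces alerts that clinicians can act on. A rule that alerts
too often buries the monitoring nurse in false alarms (alert fatigue); a
sensitive algorithm whose output is hard to interpret may alert in time and
still draw no clinical action. `htmsim` is a laboratory for exactly this
trade-off: it simulates the whole loop from patient vitals to clinician
decision, and computes the workload and agreement statistics that quantify
it. It is aimed at researchers designing telemonitoring alert strategies and
at anyone who needs well-tested reference implementations of the component
statistics.

## What it implements

**Alert algorithms** on daily series (observed days only; missing days never
alert):

- *weight-RoT* — the guideline rule of thumb: weight gain ≥ 2 kg over the
  past 3 days (current weight minus the minimum observed weight in the
  previous 3 calendar days).
- *weight-MACD* — trend detection via the difference of two exponentially
  weighted moving averages, `s_t = αx_t + (1−α)s_{t−1}`, `α = 2/(span+1)`,
  with short/long spans (default 10/30 d) and alert threshold 0.54 kg. On a
  linear trend of slope *m* the statistic converges to `m(L−S)/2`.
- *impedance-CUSUM* — a lower-sided tabular CUSUM of standardized TTI:
  `z_t = (x_t − μ_t)/σ_t` against a trailing 28-day baseline,
  `C_t = min(0, C_{t−1} + z_t + k)` with slack `k = 0.5`, alerting at
  `C_t ≤ −7` (fluid accumulation lowers impedance).

**Episodes and caseloads** — each alert becomes a 28-day review episode
ending on the alert day; within runs of consecutive-day alerts every 2nd and
3rd episode is removed (keeping ⌈L/3⌉ of a run of L); episodes are labeled by
decompensation within 28 days, split into 15 virtual caseloads, padded with
alert-free filler windows and assigned fictitious names. Symptom-diary call
reports summarize the last 5 days (none = white, once = yellow, twice or
more = red) with 2-week mood/wellbeing reference means.

**Simulated clinicians** — a latent-severity ordinal-threshold model turns
episode truth into 1–5 ratings, call decisions and four-level actions, with
per-rater noise and between-rater policy spread; review times are lognormal.

**Statistics** — raw rater-pair agreement
`agreeᵢ = Σⱼ nᵢⱼ(nᵢⱼ−1)/(nᵢ(nᵢ−1))` averaged over cases; Fleiss' kappa
`κ = (P̄ − P̄ₑ)/(1 − P̄ₑ)` on complete cases with case-resampling percentile
bootstrap CIs; review-time totals with a 5-minute per-alert cap and
episode-mean imputation of missed reviews; Mann–Whitney U arm comparisons
(exact for n ≤ 12 without ties); per-algorithm sensitivity to upcoming
decompensation and the detection-weighted action rate
(sensitivity × raised-or-high-concern rate).

**Synthetic cohort** — since the underlying clinical dataset is not public,
a generator emulates it: 91 patients, ~300 days of daily vitals, 70% male,
age 63 ± 12, BMI 29 ± 6, LVEF 31 ± 12; decompensation events ramp weight
+3 kg and TTI −5 Ω over 14 days before hospitalization; symptom diaries
escalate during the ramp; days are missing at 10%.

## Worked example

```
$ python examples/full_experiment.py
run 71f6218980abdd3e: 91 patients, 45 decompensation events

arm A (rot): 533 alert episodes, 485 after pruning
   sensitivity to decompensation 82%; review 242 +/- 7 min/rater (30 s/alert)
   kappa 0.384 (0.337-0.429); concern rate on true decompensations 52%; detection-weighted action rate 43%
arm M (macd): 363 alert episodes, 151 after pruning
   sensitivity to decompensation 93%; review 77 +/- 2 min/rater (31 s/alert)
   kappa 0.479 (0.376-0.572); concern rate on true decompensations 42%; detection-weighted action rate 39%
arm C (cusum): 701 alert episodes, 278 after pruning
   sensitivity to decompensation 91%; review 142 +/- 4 min/rater (31 s/alert)
   kappa 0.551 (0.481-0.615); concern rate on true decompensations 45%; detection-weighted action rate 41%

total review time: arm A 242 min vs arm P 109 min (Mann-Whitney two-sided p = 0.0002)
pooled arm P kappa 0.526 (0.466-0.577)
```

Reading this: the simple weight rule produces by far the most reviewed
episodes (485 vs 151/278) and therefore the highest per-rater workload
(242 min vs 109 min for the pooled advanced arm; the Mann–Whitney test calls
the difference significant), while the trend algorithms detect a larger
fraction of the injected decompensations (93%/91% vs 82%). Kappa around
0.4–0.55 means clinicians agree only modestly on which alerts deserve
action. Each `examples/*.py` script demonstrates one stage of this pipeline
and prints what its numbers mean.

A `htmsim` CLI exposes the same stages (`simulate`, `alerts`, `caseloads`,
`respond`, `agreement`, `evaluate`, `run`) on CSV/JSON flat files; see
`htmsim --help`.

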