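# Methods

## The problem being simulated

A home-telemonitoring (HTM) service for chronic heart failure receives daily
weight, blood pressure, heart rate and trans-thoracic impedance (TTI)
measurements from a panel of patients, plus twice-daily symptom
questionnaires. An alert algorithm flags days that may precede an acute
decompensation (fluid overload ending in hospitalization); a nurse or
clinician reviews each alert and decides what to do. The package simulates
this loop end to end so that three alert strategies can be compared on (a)
reviewer workload, (b) inter-rater agreement about what an alert warrants,
and (c) how much true deterioration actually draws a clinical response.

## Synthetic cohort

The generator stands in for a non-public observational dataset of 91 HF
patients monitored daily for about ten months. It reproduces that cohort's
structure and published moments, not its individual trajectories.

- **Demography.** Defaults: 91 patients, 300 days, 70% male, age 63 ± 12 y,
  BMI 29 ± 6 kg/m², LVEF 31 ± 12% (all truncated-normal draws, sampled
  independently per field — the pipeline never uses cross-correlations).
  Baseline weight is derived from BMI and a sex-dependent height draw;
  baseline TTI is 30 ± 4 Ω, in the range of healthy-to-congested
  trans-thoracic impedance.
- **Decompensation events.** A Poisson process at `decomp_rate` = 0.5 events
  per patient-year, a typical hospitalization rate for an NYHA II–IV cohort
  on loop diuretics. Event intervals never overlap within a patient. Each
  event ramps weight up by 3 kg and TTI down by 5 Ω linearly over the 14 days
  ending at the hospitalization day — magnitudes chosen to make
  pre-hospitalization trends detectable in principle, which is the premise of
  trend alerting; the source study reports no signal model, so these are free
  parameters of the generator, not estimates.
- **Recovery.** After hospitalization the fluid signal decays linearly over
  7 days (diuresis). Without this, trailing-baseline statistics would never
  re-arm between events.
- **Noise.** Weight carries a bounded random walk (sd 0.05 kg/day, clipped at
  ±1.5 kg; slow physiological drift) plus i.i.d. N(0, 0.6 kg) measurement
  noise — day-to-day scale variation including hydration and clothing, the
  realistic level at which a 2-kg/3-day rule produces its characteristic
  false-alarm burden. TTI noise is N(0, 1 Ω).
- **Missingness.** Each calendar day is observed with probability 0.9; all
  channels are missing jointly (the patient skipped the measurement session).
  No interpolation happens at generation time — every downstream algorithm
  owns its own missing-data policy.
- **Symptom diary.** Six count questions (0/1/2 = never/once/twice-or-more)
  and four yes/no questions. At baseline a count question is positive with
  probability 0.1 (then 1 w.p. 0.75, 2 w.p. 0.25, so the expected count is
  0.125); inside an event ramp each question escalates to its maximum with
  probability 0.6, and mood/wellbeing (Likert 1–5, baseline 4 ± 0.7) drop by
  1.5 points.

What the generator does **not** emulate: pharmacological dynamics, seasonal
or weekday patterns, informative missingness (sicker patients skipping
measurements), correlated demography, device drift, or NT-proBNP. Tests that
pass on this cohort therefore validate the *pipeline* — algorithm
implementations, episode logic, statistics — and the qualitative ordering of
the alert strategies, not any quantitative claim about real patients.

## Alert algorithms

All three operate on observed days only; a day with no measurement carries no
statistic and can never alert.

- **weight-RoT.** Alert on observed day *t* iff
  `weight(t) − min{observed weight on days t−3 … t−1} ≥ 2.0 kg` (inclusive).
  The window-minimum reading keeps the rule robust to gaps; a fixed-lag
  `t−3` comparison is the plausible alternative, and with daily compliance
  the two rarely differ.
- **weight-MACD.** `EWMA_short − EWMA_long` of observed weights, EWMA
  initialized at the first observation and updated once per observed
  measurement (no calendar decay across gaps). Spans default to 10/30 days —
  values in the range used for weight-trend detection; the threshold 0.54 kg
  is the published operating point. A burn-in of 14 observed days suppresses
  initialization transients.
- **impedance-CUSUM.** For observed index *i* ≥ burn-in, the trailing 28
  observed values ending at *i−1* give μ and σ (sample sd, floored at 0.5 Ω
  to avoid division blow-ups on quiet stretches); `z = (x−μ)/σ`;
  `C ← min(0, C + z + 0.5)`; alert at `C ≤ −7` (published threshold). No
  reset after an alert, so consecutive-day alerts occur — which is exactly
  what the episode-pruning rule presupposes. Window 28 d, slack 0.5 and the
  σ floor are this package's declared defaults; the source study does not
  state them.

On the default cohort these settings produce the characteristic burden
pattern: the rule of thumb alerts mostly on noise (a ~2%/day false-alarm
rate), the trend algorithms alert in sustained runs around true events. The
CUSUM's raw alert-day count exceeds the rule of thumb's *before* pruning
precisely because its alerts come in long consecutive runs; after the
every-2nd-and-3rd pruning, reviewed-episode counts order RoT > CUSUM > MACD,
the qualitative pattern of the study this emulates.

## Episodes, pruning, caseloads

An episode is the 28 calendar days ending on an alert day; alert days with
fewer than 28 days of history are dropped rather than padded (fixed-width
windows keep every downstream contract simple). Pruning keeps positions
1, 4, 7, … of each within-patient maximal run of consecutive-day alerts
(⌈L/3⌉ of a run of L) and is idempotent because survivors are ≥ 3 days
apart. Pruning is applied after the history drop; the study's ordering of
these two steps is unstated and at these alert rates the difference is
marginal.

An episode is labeled *decompensated* iff some hospitalization falls in
`(end_day, end_day + 28]`. Alert episodes are shuffled into 15 near-equal
caseloads; filler episodes (28-day alert-free windows, sampled every 7 days
along each record) are added at a 1:1 filler:alert ratio — the study calls
its filler amount "proportional" without a number; 0.5 is this package's
configurable default. Fictitious display names are drawn without reuse
within a caseload.

## Simulated raters

Latent severity per (rater, episode):
`s = baseline + discrimination·decompensated + episode_noise + rater_noise`
with defaults −0.5 + 1.5·decomp + N(0,1) + N(0,0.8). Four ordered thresholds
map *s* to the 1–5 rating; the call decision is the latent-utility rule
`slope·(s − midpoint) + ε > 0` with ε ~ Logistic(0, noise_sd), so a
noise-free panel behaves deterministically (identical policies ⇒ identical
ratings, calls and actions) while a no-signal panel responds independently
(kappa ≈ 0); for called patients three ordered cutpoints map *s* to
no-action / beginning / raised / high concern. Review times are lognormal
(log-mean 3.28, log-sd 0.5 ⇒ mean ≈ 30 s per alert, a plausible scale and
not a calibration target). Panels draw per-rater offsets (applied jointly to
all thresholds) and discriminations with sd `policy_spread`; agreement falls
smoothly as spread or noise grows. The model is the simplest mechanism that
produces the qualitative phenomena of interest — moderate kappa, higher
ratings for truly decompensating cases — and its parameters are exposed, not
fitted to any behavioral data.

## Agreement statistics

Raw agreement and Fleiss' kappa share one kernel: per case *i* with category
counts `n_ij` over `n_i` raters,
`agree_i = Σ_j n_ij(n_ij−1) / (n_i(n_i−1))`. Raw agreement is the mean of
`agree_i` over cases with ≥ 2 raters (incomplete cases included — exclusion
is flag-controlled). Kappa uses complete cases only (every panel member
responded), `κ = (P̄ − P̄_e)/(1 − P̄_e)` with `P̄_e = Σ_j p_j²` from the
pooled marginals; a single-category matrix makes κ undefined (NaN, flagged).
The four-level action set can be analysed directly or collapsed to binary
action/no-action (pooled beginning/raised/high concern).

Confidence intervals are case-resampling percentile bootstrap (n = 2000 by
default); the bootstrap variant of the source analysis is unstated and
percentile is the conservative default. Resamples on which the statistic is
undefined are redrawn and counted. Coverage of the 95% interval was checked
at ~95% on a mixture process with analytically known population kappa
(unanimous with probability q, else independent-uniform, giving κ = q
exactly).

## Workload analyses

Per-alert review times are capped at 300 s (the five-minute rule for
walked-away reviewers); a rater's missing response for an episode others
reviewed is imputed with the mean of the other raters' capped times; an
episode nobody reviewed is excluded with a warning. Totals are per rater in
minutes. Arm comparisons use the Mann–Whitney U test: exact enumeration when
both n ≤ 12 without ties, normal approximation with tie and continuity
correction otherwise (the exact and approximate branches agree to within a
few percent on moderate p-values; in the extreme tail the relative error of
any normal approximation grows, which is inherent, not an implementation
artifact). Rating distributions are tabulated per rater with across-rater
mean, sd and se = sd/√n (both dispersions emitted; figures in this
literature conventionally plot the se). The mean-rating comparison between
outcome groups reuses the same Mann–Whitney machinery. Sensitivity is the
fraction of decompensation events with ≥ 1 alert in the 28 days before
hospitalization `[hosp − 28, hosp)`; the detection-weighted action rate is
sensitivity × the raised-or-high-concern rate among responses to
decompensation episodes — the share of true deteriorations that both alert
*and* draw an active clinical response.

## Orchestration and reproducibility

`run_experiment` chains all stages: arm A (simple) reviews weight-RoT alerts
with 8 raters; the advanced arm P splits 4 + 4 raters over weight-MACD and
impedance-CUSUM sub-arms, with the pooled arm-P kappa computed on the
stacked 4-rater matrices. Every stage derives its seed as
`SeedSequence([master_seed, stage_code])` with fixed per-stage codes, so
adding stages never perturbs earlier randomness, and per-patient streams are
keyed by patient id, so growing the cohort never reshuffles existing
patients. Full runs are byte-identical for a fixed master seed (JSON with
sorted keys, fixed float formats). A full default run (91 patients × 300
days, three algorithms, 16 raters, 2000-resample bootstraps) takes a few
seconds on one CPU; the test suite's largest computation is the 500-replicate
bootstrap-coverage study (~15 s).

## Known limitations

- Generator magnitudes (event size, noise levels, event rate) are declared,
  not estimated; all conclusions from the default cohort are directional.
- The rater model has no training effects, fatigue, drop-out or
  order-of-presentation effects.
- The filler proportion and several algorithm hyper-parameters (MACD spans,
  CUSUM window/slack) are package defaults where the source analysis is
  silent; all are configurable.
- Behavioral quantities (review minutes, kappa values, p-values) produced on
  synthetic panels characterize the simulator, not human clinicians.
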