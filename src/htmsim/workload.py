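"""Workload and outcome analyses of simulated review experiments.

Covers the quantitative comparisons between study arms: per-rater total review
time (with a five-minute per-alert cap and mean imputation of missed reviews),
Mann-Whitney U tests between arms, rating distributions, action rates split by
whether the patient truly decompensated, per-algorithm alert sensitivity to
upcoming decompensations, and the detection-weighted action rate (sensitivity
x proportion of decompensation alerts drawing raised-or-high concern) that
summarizes how much true deterioration actually triggers a clinical response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .alerts import AlertSeries
from .cohort import DecompensationEvent
from .episodes import Episode
from .raters import RaterPolicy, RaterResponse, responses_to_frame

__all__ = [
    "cap_and_impute_times",
    "total_review_time",
    "mann_whitney_u",
    "rating_distribution",
    "action_by_outcome",
    "algorithm_sensitivity",
    "detection_weighted_action_rate",
    "ArmSummary",
    "summarize_arm",
]

#: Per-alert review-time cap, seconds (five minutes).
DEFAULT_CAP_S = 300.0

#: Actions counted as an active clinical concern (raised or high).
CONCERN_ACTIONS = frozenset({"raised_concern", "high_concern"})


def _rater_ids(panel: Sequence[RaterPolicy] | Sequence[str]) -> list[str]:
    return [p.rater_id if isinstance(p, RaterPolicy) else str(p) for p in panel]


def cap_and_impute_times(
    responses: Sequence[RaterResponse] | pd.DataFrame,
    panel: Sequence[RaterPolicy] | Sequence[str],
    cap_s: float = DEFAULT_CAP_S,
) -> pd.DataFrame:
    """Cap per-alert review times and impute missed reviews.

    Times above ``cap_s`` are set to ``cap_s``.  A rater with no response for
    an episode that others reviewed gets the mean of the other raters' capped
    times for that episode (``imputed`` flags those rows).  Episodes with no
    responses from anyone cannot be imputed and are excluded with a warning.

    Returns a frame with columns rater_id, episode_id, review_time_s, imputed.
    """
    frame = (
        responses.copy()
        if isinstance(responses, pd.DataFrame)
        else responses_to_frame(responses)
    )
    raters = _rater_ids(panel)
    frame = frame[frame["rater_id"].isin(raters)]
    if frame.empty:
        warnings.warn("no responses from the given panel; nothing to cap or impute")
        return pd.DataFrame(columns=["rater_id", "episode_id", "review_time_s", "imputed"])
    frame = frame[["rater_id", "episode_id", "review_time_s"]].copy()
    frame["review_time_s"] = frame["review_time_s"].clip(upper=cap_s)
    frame["imputed"] = False

    episode_means = frame.groupby("episode_id")["review_time_s"].mean()
    rows = []
    seen = set(zip(frame["rater_id"], frame["episode_id"]))
    for episode_id, mean_time in episode_means.items():
        for rater in raters:
            if (rater, episode_id) not in seen:
                rows.append(
                    {
                        "rater_id": rater,
                        "episode_id": episode_id,
                        "review_time_s": float(mean_time),
                        "imputed": True,
                    }
                )
    if rows:
        frame = pd.concat([frame, pd.DataFrame(rows)], ignore_index=True)
    return frame.sort_values(["rater_id", "episode_id"]).reset_index(drop=True)


def total_review_time(times: pd.DataFrame, rater_id: str) -> float:
    """Sum of one rater's per-alert review times, in minutes."""
    sel = times.loc[times["rater_id"] == rater_id, "review_time_s"]
    return float(sel.sum()) / 60.0


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both samples have n <= 12 and there
    are no ties, and the normal approximation with tie and continuity
    correction otherwise.  Returns (U for sample_a, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    if a.size <= 12 and b.size <= 12 and no_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def rating_distribution(
    responses: Sequence[RaterResponse] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-rater proportion of alerts given each Likert rating 1-5.

    Returns a frame indexed by rater_id with columns 1..5 summing to 1 per
    row, plus summary rows "mean", "sd" and "se" across raters (se = sd /
    sqrt(n_raters), the standard-error convention of arm-level plots).
    """
    frame = (
        responses
        if isinstance(responses, pd.DataFrame)
        else responses_to_frame(responses)
    )
    table = (
        frame.groupby("rater_id")["rating"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=[1, 2, 3, 4, 5], fill_value=0.0)
    )
    n = len(table)
    summary = pd.DataFrame(
        {
            col: [table[col].mean(), table[col].std(ddof=1), table[col].std(ddof=1) / np.sqrt(n)]
            for col in table.columns
        },
        index=["mean", "sd", "se"],
    )
    return pd.concat([table, summary])


@dataclass
class OutcomeSplit:
    """Concern rates split by true decompensation status."""

    concern_rate_decomp: float  # raised/high among responses to decompensating cases
    concern_rate_no_decomp: float
    n_decomp: int
    n_no_decomp: int
    mean_rating_decomp: float
    mean_rating_no_decomp: float

    @property
    def mean_rating_difference(self) -> float:
        return self.mean_rating_decomp - self.mean_rating_no_decomp


def action_by_outcome(
    responses: Sequence[RaterResponse],
    episodes: Sequence[Episode],
) -> OutcomeSplit:
    """Proportion of responses with raised-or-high concern, split by whether
    the episode's patient decompensated within the labeling horizon."""
    label = {ep.episode_id: ep.decompensated for ep in episodes}
    concern = {True: 0, False: 0}
    total = {True: 0, False: 0}
    rating_sum = {True: 0.0, False: 0.0}
    for r in responses:
        if r.episode_id not in label or label[r.episode_id] is None:
            raise ValidationError(f"episode {r.episode_id} is unlabeled")
        d = bool(label[r.episode_id])
        total[d] += 1
        rating_sum[d] += r.rating
        if r.action in CONCERN_ACTIONS:
            concern[d] += 1
    for d in (True, False):
        if total[d] == 0:
            warnings.warn(
                f"no responses in the decompensated={d} stratum; rate undefined"
            )
    return OutcomeSplit(
        concern_rate_decomp=concern[True] / total[True] if total[True] else float("nan"),
        concern_rate_no_decomp=concern[False] / total[False] if total[False] else float("nan"),
        n_decomp=total[True],
        n_no_decomp=total[False],
        mean_rating_decomp=rating_sum[True] / total[True] if total[True] else float("nan"),
        mean_rating_no_decomp=rating_sum[False] / total[False] if total[False] else float("nan"),
    )


def algorithm_sensitivity(
    alerts: Mapping[str, AlertSeries],
    events: Sequence[DecompensationEvent],
    horizon: int = 28,
) -> float:
    """Fraction of decompensation events preceded by at least one alert in the
    ``horizon`` days before hospitalization ([hosp - horizon, hosp))."""
    if not events:
        warnings.warn("no decompensation events; sensitivity undefined")
        return float("nan")
    detected = 0
    for ev in events:
        series = alerts.get(ev.patient_id)
        if series is None:
            continue
        h = ev.hospitalization_day
        if any(h - horizon <= d < h for d in series.alert_days.tolist()):
            detected += 1
    return detected / len(events)


def detection_weighted_action_rate(sensitivity: float, action_rate: float) -> float:
    """sensitivity x action rate: the share of decompensations that both alert
    and draw a raised-or-high-concern response."""
    for name, v in (("sensitivity", sensitivity), ("action_rate", action_rate)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    return sensitivity * action_rate


@dataclass
class ArmSummary:
    """Arm-level review workload and response mix."""

    arm: str
    n_raters: int
    n_alert_episodes: int
    total_minutes_per_rater: dict[str, float]
    total_minutes_mean: float
    total_minutes_sd: float
    per_alert_seconds_mean: float
    per_alert_seconds_sd: float
    rating_proportions: pd.DataFrame = field(repr=False)
    action_proportion: float  # any concern (beginning/raised/high)
    outcome_split: OutcomeSplit


def summarize_arm(
    arm: str,
    responses: Sequence[RaterResponse],
    episodes: Sequence[Episode],
    panel: Sequence[RaterPolicy] | Sequence[str],
    cap_s: float = DEFAULT_CAP_S,
) -> ArmSummary:
    """Compute the full arm-level summary from raw responses."""
    raters = _rater_ids(panel)
    times = cap_and_impute_times(responses, panel, cap_s=cap_s)
    totals = {r: total_review_time(times, r) for r in raters}
    tot = np.array(list(totals.values()))
    per_alert = times.groupby("rater_id")["review_time_s"].mean().reindex(raters)
    action_prop = float(
        np.mean([r.action != "no_action" for r in responses])
    ) if responses else float("nan")
    return ArmSummary(
        arm=arm,
        n_raters=len(raters),
        n_alert_episodes=times["episode_id"].nunique(),
        total_minutes_per_rater=totals,
        total_minutes_mean=float(tot.mean()),
        total_minutes_sd=float(tot.std(ddof=1)) if len(tot) > 1 else 0.0,
        per_alert_seconds_mean=float(per_alert.mean()),
        per_alert_seconds_sd=float(per_alert.std(ddof=1)) if len(per_alert) > 1 else 0.0,
        rating_proportions=rating_distribution(responses),
        action_proportion=action_prop,
        outcome_split=action_by_outcome(responses, episodes),
    )
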