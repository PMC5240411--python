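"""Simulated clinician panels.

Real inter-rater experiments need recruited clinicians; this module replaces
them with a latent-severity ordinal-threshold model so that the agreement and
workload statistics downstream are exercisable end to end.

Each alert episode has a latent severity

    s = baseline + discrimination * decompensated + episode noise + rater noise

where the episode noise is shared by all raters (the case itself looks more or
less worrying) and the rater noise is idiosyncratic.  A rater's four ordered
``thresholds`` discretize s into the 1-5 meaningfulness rating; the decision to
"call" the patient is Bernoulli with a logistic probability in s; for called
patients three ordered ``action_cutpoints`` map s to the four action
categories (no action / beginning / raised / high concern).  Review times are
lognormal per alert.  The model is a mechanism, not a fit: its parameters are
exposed, and agreement falls smoothly as ``noise_sd`` or the between-rater
policy spread grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .episodes import Caseload, Episode

__all__ = [
    "ACTIONS",
    "RaterPolicy",
    "SeverityModel",
    "RaterResponse",
    "make_panel",
    "simulate_responses",
    "responses_to_frame",
    "responses_from_frame",
]

#: Action categories in increasing order of concern.
ACTIONS = ("no_action", "beginning_concern", "raised_concern", "high_concern")


@dataclass(frozen=True)
class RaterPolicy:
    """One simulated clinician's decision policy."""

    rater_id: str
    discrimination: float = 1.5  # shift in severity for truly decompensating cases
    thresholds: tuple[float, float, float, float] = (-1.0, 0.0, 1.0, 2.0)
    action_cutpoints: tuple[float, float, float] = (0.0, 1.0, 2.0)
    noise_sd: float = 0.8
    time_log_mean: float = 3.28  # log-seconds; exp(3.28 + 0.5^2/2) ~ 30 s per alert
    time_log_sd: float = 0.5
    call_probability_slope: float = 2.0
    call_midpoint: float = 0.0

    def __post_init__(self):
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValidationError("thresholds must be strictly increasing")
        if list(self.action_cutpoints) != sorted(set(self.action_cutpoints)):
            raise ValidationError("action_cutpoints must be strictly increasing")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SeverityModel:
    """Episode-level component of latent severity."""

    baseline: float = -0.5
    episode_noise_sd: float = 1.0


@dataclass(frozen=True)
class RaterResponse:
    rater_id: str
    episode_id: str
    rating: int  # 1-5 Likert meaningfulness
    called: bool
    action: str  # one of ACTIONS; "no_action" whenever called is False
    review_time_s: float

    def __post_init__(self):
        if not 1 <= self.rating <= 5:
            raise ValidationError("rating must be in 1..5")
        if self.action not in ACTIONS:
            raise ValidationError(f"unknown action {self.action!r}")
        if not self.called and self.action != "no_action":
            raise ValidationError("action must be no_action when not called")
        if self.review_time_s <= 0:
            raise ValidationError("review_time_s must be > 0")


def make_panel(
    n_raters: int,
    policy_spread: float = 0.3,
    seed: int = 0,
    base: RaterPolicy | None = None,
    prefix: str = "R",
) -> list[RaterPolicy]:
    """Draw a panel of rater policies around shared means.

    ``policy_spread`` scales normal perturbations of each rater's severity
    offset (applied to all thresholds and cutpoints jointly) and
    discrimination; spread 0 gives identical policies.
    """
    if n_raters < 2:
        raise ValidationError("n_raters must be >= 2 (agreement is undefined otherwise)")
    base = base or RaterPolicy(rater_id="base")
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_raters):
        offset = rng.normal(0.0, policy_spread)
        disc = max(0.0, base.discrimination + rng.normal(0.0, policy_spread))
        panel.append(
            replace(
                base,
                rater_id=f"{prefix}{i + 1:02d}",
                discrimination=disc,
                thresholds=tuple(t + offset for t in base.thresholds),
                action_cutpoints=tuple(c + offset for c in base.action_cutpoints),
            )
        )
    return panel


def _alert_episodes(caseloads: Sequence[Caseload]) -> list[Episode]:
    eps: list[Episode] = []
    for cl in caseloads:
        eps.extend(cl.alert_episodes)
    return eps


def simulate_responses(
    panel: Sequence[RaterPolicy],
    caseloads: Sequence[Caseload],
    severity_model: SeverityModel | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> list[RaterResponse]:
    """One response per rater per alert episode (filler is never rated).

    ``missing_rate`` > 0 drops responses at random, producing the incomplete
    cases that the complete-case rule of the kappa computation must handle.
    Deterministic for fixed seed.
    """
    severity_model = severity_model or SeverityModel()
    episodes = _alert_episodes(caseloads)
    for ep in episodes:
        if ep.decompensated is None:
            raise ValidationError(f"episode {ep.episode_id} has no decompensation label")
    rng = np.random.default_rng(seed)
    episode_noise = rng.normal(0.0, severity_model.episode_noise_sd, size=len(episodes))
    responses: list[RaterResponse] = []
    for policy in panel:
        for j, ep in enumerate(episodes):
            s = (
                severity_model.baseline
                + policy.discrimination * float(ep.decompensated)
                + episode_noise[j]
                + rng.normal(0.0, policy.noise_sd)
            )
            rating = 1 + int(np.searchsorted(policy.thresholds, s, side="right"))
            # latent-utility call decision: logistic idiosyncrasy scaled by the
            # rater's own noise, so a noise-free rater calls deterministically
            # above the midpoint and a pure-noise rater calls independently
            eps = rng.logistic(0.0, policy.noise_sd) if policy.noise_sd > 0 else 0.0
            called = bool(
                policy.call_probability_slope * (s - policy.call_midpoint) + eps > 0
            )
            if called:
                k = int(np.searchsorted(policy.action_cutpoints, s, side="right"))
                action = ACTIONS[k]
            else:
                action = "no_action"
            time_s = float(rng.lognormal(policy.time_log_mean, policy.time_log_sd))
            if missing_rate > 0 and rng.random() < missing_rate:
                continue
            responses.append(
                RaterResponse(
                    rater_id=policy.rater_id,
                    episode_id=ep.episode_id,
                    rating=rating,
                    called=called,
                    action=action,
                    review_time_s=time_s,
                )
            )
    return responses


def responses_to_frame(responses: Sequence[RaterResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rater_id": [r.rater_id for r in responses],
            "episode_id": [r.episode_id for r in responses],
            "rating": [r.rating for r in responses],
            "called": [r.called for r in responses],
            "action": [r.action for r in responses],
            "review_time_s": [r.review_time_s for r in responses],
        }
    )


def responses_from_frame(frame: pd.DataFrame) -> list[RaterResponse]:
    return [
        RaterResponse(
            rater_id=str(row.rater_id),
            episode_id=str(row.episode_id),
            rating=int(row.rating),
            called=bool(row.called),
            action=str(row.action),
            review_time_s=float(row.review_time_s),
        )
        for row in frame.itertuples()
    ]
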