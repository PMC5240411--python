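"""Review episodes and virtual caseloads.

An *episode* is the unit a clinician reviews: a 28-day window of monitoring
data ending on an alert day.  Alert days with fewer than 28 days of history
are dropped so every episode has the full fixed-width window.  When a patient
alerts on consecutive days, only every third episode is kept (the 2nd and 3rd
of each run are removed) so the same deterioration period is not shown twice
within a caseload.

A *caseload* is a batch of episodes presented together for review: the alert
episodes (split randomly into ``n_caseloads`` near-equal groups) padded with
"filler" episodes containing no alerts, each episode carrying a fictitious
patient name.  The filler has no analytic role; it makes the batch look like a
real patient panel.

The *call report* summarizes the symptom diary the way a follow-up phone call
would: the answers of the previous five days with count answers color-coded
(none = white, once = yellow, twice or more = red) and reference means of mood
and wellbeing over the preceding two weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from ._errors import ValidationError
from .alerts import AlertSeries
from .cohort import (
    COUNT_QUESTIONS,
    YESNO_QUESTIONS,
    DecompensationEvent,
    SymptomDiary,
    VitalsSeries,
)

__all__ = [
    "Episode",
    "Caseload",
    "CallReport",
    "EPISODE_WINDOW",
    "build_episodes",
    "prune_consecutive",
    "label_decompensation",
    "label_all",
    "build_filler_pool",
    "assemble_caseloads",
    "make_call_report",
    "default_name_pool",
]

#: Length of a review episode in calendar days.
EPISODE_WINDOW = 28


@dataclass(frozen=True)
class Episode:
    episode_id: str
    patient_id: str
    end_day: int
    window: int = EPISODE_WINDOW  # days; window covers [end_day-window+1, end_day]
    is_alert_episode: bool = True
    algorithm: str | None = None
    decompensated: bool | None = None  # None = not yet labeled
    display_name: str | None = None

    @property
    def start_day(self) -> int:
        return self.end_day - self.window + 1


@dataclass(frozen=True)
class Caseload:
    """One review batch: alert episodes first, then filler."""

    caseload_id: int
    arm: str
    episodes: tuple[Episode, ...]

    @property
    def alert_episodes(self) -> tuple[Episode, ...]:
        return tuple(e for e in self.episodes if e.is_alert_episode)

    @property
    def filler_episodes(self) -> tuple[Episode, ...]:
        return tuple(e for e in self.episodes if not e.is_alert_episode)


def build_episodes(
    alerts: AlertSeries,
    vitals: VitalsSeries,
    window: int = EPISODE_WINDOW,
) -> list[Episode]:
    """One episode per alert day, each spanning the ``window`` days ending on
    the alert; alert days with less than a full window of history are dropped."""
    first_day = int(vitals.day.min()) if vitals.day.size else 0
    episodes = []
    for d in alerts.alert_days.tolist():
        if d - window + 1 < first_day:
            continue
        episodes.append(
            Episode(
                episode_id=f"{alerts.patient_id}:{alerts.algorithm}:{d}",
                patient_id=alerts.patient_id,
                end_day=int(d),
                window=window,
                is_alert_episode=True,
                algorithm=alerts.algorithm,
            )
        )
    return episodes


def prune_consecutive(episodes: Sequence[Episode]) -> list[Episode]:
    """Within each patient's maximal runs of consecutive-day alerts, keep the
    1st, 4th, 7th, ... episode (drop every 2nd and 3rd).  Idempotent on its own
    output because surviving episodes are at least 3 days apart."""
    kept: list[Episode] = []
    by_patient: dict[str, list[Episode]] = {}
    for ep in episodes:
        by_patient.setdefault(ep.patient_id, []).append(ep)
    for pid in sorted(by_patient):
        eps = sorted(by_patient[pid], key=lambda e: e.end_day)
        run_pos = 0
        prev_day = None
        for ep in eps:
            if prev_day is not None and ep.end_day == prev_day + 1:
                run_pos += 1
            else:
                run_pos = 0
            if run_pos % 3 == 0:
                kept.append(ep)
            prev_day = ep.end_day
    kept.sort(key=lambda e: (e.patient_id, e.end_day))
    return kept


def label_decompensation(
    episode: Episode,
    events: Sequence[DecompensationEvent],
    horizon: int = EPISODE_WINDOW,
) -> bool:
    """True iff the patient is hospitalized within ``horizon`` days after the
    episode ends (hospitalization_day in (end_day, end_day + horizon])."""
    return any(
        ev.patient_id == episode.patient_id
        and episode.end_day < ev.hospitalization_day <= episode.end_day + horizon
        for ev in events
    )


def label_all(
    episodes: Sequence[Episode],
    events: Sequence[DecompensationEvent],
    horizon: int = EPISODE_WINDOW,
) -> list[Episode]:
    """Return episodes with their ``decompensated`` flag filled in."""
    return [
        replace(ep, decompensated=label_decompensation(ep, events, horizon))
        for ep in episodes
    ]


def build_filler_pool(
    vitals: Mapping[str, VitalsSeries],
    alerts: Mapping[str, AlertSeries],
    window: int = EPISODE_WINDOW,
    stride: int = 7,
) -> list[Episode]:
    """Candidate filler episodes: ``window``-day segments of each patient's
    record containing no alert day for the given algorithm, taken every
    ``stride`` days (overlapping candidates are acceptable; the filler only
    dresses the caseload and is never analysed)."""
    pool: list[Episode] = []
    for pid in sorted(vitals):
        series = vitals[pid]
        alert_days = set(alerts[pid].alert_days.tolist()) if pid in alerts else set()
        algorithm = alerts[pid].algorithm if pid in alerts else None
        first = int(series.day.min())
        last = int(series.day.max())
        for end in range(first + window - 1, last + 1, stride):
            if not any(end - window + 1 <= d <= end for d in alert_days):
                pool.append(
                    Episode(
                        episode_id=f"{pid}:filler:{end}",
                        patient_id=pid,
                        end_day=end,
                        window=window,
                        is_alert_episode=False,
                        algorithm=algorithm,
                    )
                )
    return pool


def default_name_pool() -> list[str]:
    """A pool of fictitious patient names for caseload display."""
    first = [
        "Alice", "Brian", "Carol", "David", "Elena", "Frank", "Grace", "Henry",
        "Irene", "James", "Karen", "Liam", "Mary", "Nigel", "Olive", "Peter",
        "Queenie", "Robert", "Susan", "Thomas", "Una", "Victor", "Wendy", "Xavier",
        "Yvonne", "Zach",
    ]
    last = [
        "Appleton", "Burton", "Clarke", "Dawson", "Ellis", "Fletcher", "Graham",
        "Hodges", "Inglis", "Jarvis", "Kemp", "Lawson", "Mercer", "Norton",
        "Osborne", "Padgett", "Quinn", "Rowley", "Sutton", "Thorne",
    ]
    return [f"{f} {l}" for l in last for f in first]


def assemble_caseloads(
    alert_episodes: Sequence[Episode],
    non_alert_pool: Sequence[Episode],
    n_caseloads: int = 15,
    filler_fraction: float = 0.5,
    name_pool: Sequence[str] | None = None,
    seed: int = 0,
    arm: str = "",
) -> list[Caseload]:
    """Randomly split the alert episodes into ``n_caseloads`` near-equal groups
    and pad each with filler so filler / (alert + filler) ~= ``filler_fraction``.

    Filler is drawn uniformly without replacement from ``non_alert_pool``;
    fictitious names are assigned without reuse within a caseload.  Output is
    deterministic for a fixed seed, with alert episodes listed first.
    """
    if not (0 <= filler_fraction < 1):
        raise ValidationError("filler_fraction must be in [0, 1)")
    if n_caseloads < 1:
        raise ValidationError("n_caseloads must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(name_pool) if name_pool is not None else default_name_pool()

    alert_eps = list(alert_episodes)
    order = rng.permutation(len(alert_eps))
    shuffled = [alert_eps[i] for i in order]
    groups: list[list[Episode]] = [
        list(g) for g in np.array_split(np.arange(len(shuffled)), n_caseloads)
    ]
    group_eps = [[shuffled[int(i)] for i in g] for g in groups]

    # total filler needed across caseloads, drawn once without replacement
    filler_counts = [
        int(round(len(g) * filler_fraction / (1 - filler_fraction))) for g in group_eps
    ]
    total_filler = sum(filler_counts)
    if total_filler > len(non_alert_pool):
        raise ValidationError(
            f"filler pool too small: need {total_filler}, have {len(non_alert_pool)} "
            f"(short by {total_filler - len(non_alert_pool)})"
        )
    filler_order = rng.permutation(len(non_alert_pool))
    filler_iter = iter([non_alert_pool[int(i)] for i in filler_order])

    caseloads: list[Caseload] = []
    for cid, (g, n_fill) in enumerate(zip(group_eps, filler_counts), start=1):
        fillers = [next(filler_iter) for _ in range(n_fill)]
        members = list(g) + fillers
        if len(members) > len(names):
            raise ValidationError(
                f"name pool too small: caseload {cid} has {len(members)} episodes, "
                f"pool has {len(names)} names"
            )
        chosen = rng.choice(len(names), size=len(members), replace=False)
        named = [
            replace(ep, display_name=names[int(j)]) for ep, j in zip(members, chosen)
        ]
        caseloads.append(Caseload(caseload_id=cid, arm=arm, episodes=tuple(named)))
    return caseloads


_COLOR_MAP = {0: "white", 1: "yellow", 2: "red"}


def _color(value: float) -> str:
    if np.isnan(value):
        return "missing"
    return _COLOR_MAP[min(int(value), 2)]


@dataclass
class CallReport:
    """Content of a simulated follow-up call on a given day."""

    patient_id: str
    day: int
    five_day_symptoms: dict[str, list[float]]  # question -> values for day-4..day
    color_codes: dict[str, list[str]]  # count questions only
    mood_ref: float | None  # mean mood over day-14..day-1, observed entries
    wellbeing_ref: float | None


def make_call_report(diary: SymptomDiary, day: int) -> CallReport:
    """Five-day symptom overview with two-week mood/wellbeing reference means.

    With fewer than 14 days of diary history before ``day`` the reference
    values are marked unavailable (None).
    """
    data = diary.data.set_index("day")
    window_days = list(range(day - 4, day + 1))
    symptoms: dict[str, list[float]] = {}
    colors: dict[str, list[str]] = {}
    questions = ("mood", "wellbeing") + COUNT_QUESTIONS + YESNO_QUESTIONS
    for q in questions:
        vals = [
            float(data.at[d, q]) if d in data.index and not np.isnan(data.at[d, q])
            else float("nan")
            for d in window_days
        ]
        symptoms[q] = vals
        if q in COUNT_QUESTIONS:
            colors[q] = [_color(v) for v in vals]

    first_day = int(data.index.min()) if len(data) else day
    if day - first_day < 14:
        mood_ref = wellbeing_ref = None
    else:
        ref_days = [d for d in range(day - 14, day) if d in data.index]
        mood_vals = data.loc[ref_days, "mood"].dropna()
        well_vals = data.loc[ref_days, "wellbeing"].dropna()
        mood_ref = float(mood_vals.mean()) if len(mood_vals) else None
        wellbeing_ref = float(well_vals.mean()) if len(well_vals) else None
    return CallReport(
        patient_id=diary.patient_id,
        day=day,
        five_day_symptoms=symptoms,
        color_codes=colors,
        mood_ref=mood_ref,
        wellbeing_ref=wellbeing_ref,
    )
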