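"""Synthetic heart-failure telemonitoring cohort.

Generates a cohort of chronic heart-failure patients under daily home
telemonitoring: demographic profiles, decompensation (acute fluid-overload)
events, daily vitals (weight, blood pressure, heart rate, trans-thoracic
impedance) on a calendar-day grid with missing days, and twice-daily-style
symptom diaries.

The signal model is deliberately simple.  Each decompensation event ramps
weight up by ``weight_gain_total`` kg and trans-thoracic impedance (TTI) down
by ``impedance_drop_total`` ohm, linearly over ``ramp_days`` days ending at the
hospitalization day (fluid accumulates, raising tissue conductivity and hence
lowering impedance); after hospitalization the fluid signal recovers linearly
over ``recovery_days`` days.  Weight additionally carries a bounded random walk
(slow physiological drift) and i.i.d. Gaussian measurement noise.  Days are
missing jointly across channels with probability ``1 - compliance``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigError, ValidationError

__all__ = [
    "CohortConfig",
    "PatientProfile",
    "DecompensationEvent",
    "VitalsSeries",
    "SymptomDiary",
    "COUNT_QUESTIONS",
    "YESNO_QUESTIONS",
    "generate_cohort",
    "generate_vitals",
    "generate_symptom_diary",
    "simulate_cohort",
    "CohortData",
    "vitals_to_csv",
    "vitals_from_csv",
    "diary_to_csv",
    "profiles_to_json",
    "events_to_json",
]

#: Symptom-diary questions answered as a frequency count (0 = never,
#: 1 = once, 2 = twice or more).
COUNT_QUESTIONS = (
    "night_toilet",
    "cough",
    "night_breathlessness",
    "night_chest_pain",
    "rest_breathlessness",
    "palpitations",
)

#: Symptom-diary questions answered yes/no.
YESNO_QUESTIONS = (
    "ankle_swelling",
    "medication_change",
    "exercise_better",
    "light_headed",
)

_AETIOLOGIES = ("ischaemic", "dilated cardiomyopathy", "hypertensive", "valvular", "other")
_COMORBIDITIES = (
    "atrial fibrillation",
    "diabetes",
    "hypertension",
    "COPD",
    "renal impairment",
    "anaemia",
)


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort generator.

    Defaults emulate the monitoring study the pipeline targets: 91 patients
    followed for roughly ten months with daily weight, blood pressure, heart
    rate and TTI, a cohort that is 70% male with age 63 +/- 12 years,
    BMI 29 +/- 6 kg/m^2 and LVEF 31 +/- 12 %.
    """

    n_patients: int = 91
    duration_days: int = 300
    #: decompensation events per patient-year (Poisson rate)
    decomp_rate: float = 0.5
    #: probability a monitoring day is observed
    compliance: float = 0.9
    # measurement noise (sd of i.i.d. Gaussian noise per observed day)
    weight_sd: float = 0.6
    tti_sd: float = 1.0
    sbp_sd: float = 8.0
    hr_sd: float = 5.0
    # demography moments
    male_fraction: float = 0.70
    age_mean: float = 63.0
    age_sd: float = 12.0
    bmi_mean: float = 29.0
    bmi_sd: float = 6.0
    lvef_mean: float = 31.0
    lvef_sd: float = 12.0
    # event signal model
    weight_gain_total: float = 3.0
    impedance_drop_total: float = 5.0
    ramp_days: int = 14
    recovery_days: int = 7
    # slow physiological weight drift: bounded random walk
    drift_sd: float = 0.05
    drift_bound: float = 1.5
    # symptom diary
    symptom_baseline_prob: float = 0.1
    symptom_event_prob: float = 0.6
    mood_baseline: float = 4.0
    mood_sd: float = 0.7
    mood_event_drop: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients", "must be >= 1")
        if self.duration_days < 1:
            raise ConfigError("duration_days", "must be >= 1")
        if self.decomp_rate < 0:
            raise ConfigError("decomp_rate", "must be >= 0")
        if not (0 < self.compliance <= 1):
            raise ConfigError("compliance", "must be in (0, 1]")
        for name in ("weight_sd", "tti_sd", "sbp_sd", "hr_sd", "age_sd", "bmi_sd",
                     "lvef_sd", "drift_sd", "mood_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        if not (0 <= self.male_fraction <= 1):
            raise ConfigError("male_fraction", "must be in [0, 1]")
        if self.weight_gain_total <= 0:
            raise ConfigError("weight_gain_total", "must be > 0")
        if self.impedance_drop_total <= 0:
            raise ConfigError("impedance_drop_total", "must be > 0")
        if self.ramp_days < 1:
            raise ConfigError("ramp_days", "must be >= 1")
        if self.recovery_days < 0:
            raise ConfigError("recovery_days", "must be >= 0")
        for name in ("symptom_baseline_prob", "symptom_event_prob"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigError(name, "must be in [0, 1]")


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    sex: str  # "male" | "female"
    age: float  # years
    bmi: float  # kg/m^2
    lvef: float  # percent
    nyha: str  # "II" | "III" | "IV"
    aetiology: str
    comorbidities: tuple[str, ...]
    baseline_weight: float  # kg
    baseline_impedance: float  # ohm

    def __post_init__(self):
        if self.age <= 0:
            raise ValidationError(f"{self.patient_id}: age must be > 0")
        if not (10 <= self.bmi <= 60):
            raise ValidationError(f"{self.patient_id}: bmi out of [10, 60]")
        if not (5 <= self.lvef <= 75):
            raise ValidationError(f"{self.patient_id}: lvef out of [5, 75]")
        if self.baseline_weight <= 0 or self.baseline_impedance <= 0:
            raise ValidationError(f"{self.patient_id}: baselines must be > 0")


@dataclass(frozen=True)
class DecompensationEvent:
    """One fluid-overload event: accumulation begins at ``onset_day`` and ends
    in hospitalization at ``hospitalization_day``."""

    patient_id: str
    onset_day: int
    hospitalization_day: int
    weight_gain_total: float  # kg
    impedance_drop_total: float  # ohm
    ramp_days: int

    def __post_init__(self):
        if self.onset_day >= self.hospitalization_day:
            raise ValidationError("onset_day must precede hospitalization_day")
        if self.weight_gain_total <= 0 or self.impedance_drop_total <= 0:
            raise ValidationError("event magnitudes must be > 0")
        if self.ramp_days < 1:
            raise ValidationError("ramp_days must be >= 1")


@dataclass
class VitalsSeries:
    """One patient's daily measurements on a calendar-day grid.

    One entry per calendar day of the monitoring span; ``NaN`` marks a missing
    (non-compliant) day.  All channels are missing jointly.
    """

    patient_id: str
    day: np.ndarray  # int, strictly increasing, one per calendar day
    weight: np.ndarray  # kg
    sbp: np.ndarray  # mmHg
    dbp: np.ndarray  # mmHg
    hr: np.ndarray  # bpm
    tti: np.ndarray  # ohm

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.weight)

    def observed(self, channel: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (days, values) restricted to non-missing entries of a channel."""
        values = getattr(self, channel)
        mask = ~np.isnan(values)
        return self.day[mask], values[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "day": self.day,
                "weight": self.weight,
                "sbp": self.sbp,
                "dbp": self.dbp,
                "hr": self.hr,
                "tti": self.tti,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VitalsSeries":
        ids = frame["patient_id"].unique()
        if len(ids) != 1:
            raise ValidationError("vitals frame must contain exactly one patient")
        frame = frame.sort_values("day")
        return cls(
            patient_id=str(ids[0]),
            day=frame["day"].to_numpy(dtype=int),
            weight=frame["weight"].to_numpy(dtype=float),
            sbp=frame["sbp"].to_numpy(dtype=float),
            dbp=frame["dbp"].to_numpy(dtype=float),
            hr=frame["hr"].to_numpy(dtype=float),
            tti=frame["tti"].to_numpy(dtype=float),
        )


@dataclass
class SymptomDiary:
    """One patient's daily symptom questionnaire answers.

    ``data`` has one row per monitored day with columns ``day``, ``mood``,
    ``wellbeing`` (Likert 1-5), the six count questions (0/1/2 = never / once /
    twice or more) and the four yes/no questions (0/1).  Missing days carry NaN.
    """

    patient_id: str
    data: pd.DataFrame


def _sub_seed(master: int, patient_id: str, stream: int) -> np.random.Generator:
    """Per-patient, per-stream RNG: stable under cohort-level changes."""
    tag = zlib.crc32(patient_id.encode())
    return np.random.default_rng(np.random.SeedSequence([master, tag, stream]))


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientProfile], list[DecompensationEvent]]:
    """Draw patient profiles and decompensation events for the whole cohort.

    Events per patient follow a Poisson process at ``decomp_rate`` events per
    patient-year; event intervals (fluid ramp through hospitalization) never
    overlap within a patient.  Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    profiles: list[PatientProfile] = []
    events: list[DecompensationEvent] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        sex = "male" if rng.random() < config.male_fraction else "female"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 20, 95))
        bmi = float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), 15, 55))
        lvef = float(np.clip(rng.normal(config.lvef_mean, config.lvef_sd), 10, 70))
        nyha = str(rng.choice(["II", "III", "IV"], p=[0.45, 0.45, 0.10]))
        aetiology = str(rng.choice(_AETIOLOGIES, p=[0.5, 0.2, 0.15, 0.1, 0.05]))
        n_comorb = int(rng.integers(0, 4))
        comorb = tuple(
            sorted(rng.choice(_COMORBIDITIES, size=n_comorb, replace=False).tolist())
        )
        height_m = rng.normal(1.74 if sex == "male" else 1.62, 0.07)
        baseline_weight = float(np.clip(bmi * height_m**2, 40, 180))
        baseline_impedance = float(np.clip(rng.normal(30.0, 4.0), 15, 60))
        profiles.append(
            PatientProfile(
                patient_id=pid,
                sex=sex,
                age=age,
                bmi=bmi,
                lvef=lvef,
                nyha=nyha,
                aetiology=aetiology,
                comorbidities=comorb,
                baseline_weight=baseline_weight,
                baseline_impedance=baseline_impedance,
            )
        )
        events.extend(_draw_events(pid, config, rng))
    return profiles, events


def _draw_events(
    pid: str, config: CohortConfig, rng: np.random.Generator
) -> list[DecompensationEvent]:
    expected = config.decomp_rate * config.duration_days / 365.0
    n_events = int(rng.poisson(expected))
    if n_events == 0:
        return []
    events: list[DecompensationEvent] = []
    taken: list[tuple[int, int]] = []
    attempts = 0
    # hospitalization must leave room for the full ramp before it and any
    # recovery tail inside the span
    lo = config.ramp_days
    hi = max(lo + 1, config.duration_days - 1 - config.recovery_days)
    while len(events) < n_events and attempts < 200:
        attempts += 1
        hosp = int(rng.integers(lo, hi))
        onset = hosp - config.ramp_days
        span = (onset, hosp + config.recovery_days)
        if any(not (span[1] < a or span[0] > b) for a, b in taken):
            continue
        taken.append(span)
        events.append(
            DecompensationEvent(
                patient_id=pid,
                onset_day=onset,
                hospitalization_day=hosp,
                weight_gain_total=config.weight_gain_total,
                impedance_drop_total=config.impedance_drop_total,
                ramp_days=config.ramp_days,
            )
        )
    events.sort(key=lambda e: e.hospitalization_day)
    return events


def _event_ramp(days: np.ndarray, events: Sequence[DecompensationEvent],
                recovery_days: int) -> np.ndarray:
    """Per-event fractional fluid load in [0, 1] per day, stacked over events:
    linear accrual over the ramp, linear recovery after hospitalization."""
    frac = np.zeros((len(events), len(days)), dtype=float)
    for i, ev in enumerate(events):
        start = ev.hospitalization_day - ev.ramp_days
        up = np.clip((days - start) / ev.ramp_days, 0.0, 1.0)
        up[days > ev.hospitalization_day] = 0.0
        frac[i] = up
        if recovery_days > 0:
            post = (days > ev.hospitalization_day) & (
                days <= ev.hospitalization_day + recovery_days
            )
            frac[i, post] = 1.0 - (days[post] - ev.hospitalization_day) / recovery_days
    return frac


def generate_vitals(
    profile: PatientProfile,
    events: Sequence[DecompensationEvent],
    config: CohortConfig,
    seed: int | None = None,
) -> VitalsSeries:
    """Simulate one patient's daily vitals over the monitoring span.

    weight = baseline + bounded random-walk drift + event ramp + noise;
    tti = baseline - event ramp + noise.  Days are missing jointly with
    probability ``1 - compliance``.
    """
    config.validate()
    for ev in events:
        if ev.patient_id != profile.patient_id:
            raise ValidationError(
                f"event for {ev.patient_id} passed with patient {profile.patient_id}"
            )
        if ev.onset_day < 0 or ev.hospitalization_day >= config.duration_days:
            raise ValidationError(
                f"{profile.patient_id}: event [{ev.onset_day}, "
                f"{ev.hospitalization_day}] outside monitoring span"
            )
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else _sub_seed(config.seed, profile.patient_id, 1)
    )
    n = config.duration_days
    days = np.arange(n)

    drift = np.zeros(n)
    if config.drift_sd > 0:
        steps = rng.normal(0.0, config.drift_sd, size=n)
        level = 0.0
        for t in range(1, n):
            level = float(np.clip(level + steps[t], -config.drift_bound, config.drift_bound))
            drift[t] = level

    frac = _event_ramp(days, events, config.recovery_days)
    gains = np.array([ev.weight_gain_total for ev in events])
    drops = np.array([ev.impedance_drop_total for ev in events])
    weight_gain = gains @ frac if events else np.zeros(n)
    tti_drop = drops @ frac if events else np.zeros(n)
    hr_load = frac.sum(axis=0) if events else np.zeros(n)

    weight = profile.baseline_weight + drift + weight_gain + rng.normal(0, config.weight_sd, n)
    tti = profile.baseline_impedance - tti_drop + rng.normal(0, config.tti_sd, n)
    sbp_base = rng.normal(120.0, 10.0)
    dbp_base = rng.normal(75.0, 7.0)
    hr_base = rng.normal(72.0, 8.0)
    sbp = sbp_base + rng.normal(0, config.sbp_sd, n)
    dbp = dbp_base + rng.normal(0, config.sbp_sd * 0.6, n)
    hr = hr_base + hr_load * 8.0 + rng.normal(0, config.hr_sd, n)

    missing = rng.random(n) >= config.compliance
    for arr in (weight, sbp, dbp, hr, tti):
        arr[missing] = np.nan
    return VitalsSeries(
        patient_id=profile.patient_id,
        day=days,
        weight=weight,
        sbp=sbp,
        dbp=dbp,
        hr=hr,
        tti=tti,
    )


def generate_symptom_diary(
    profile: PatientProfile,
    events: Sequence[DecompensationEvent],
    config: CohortConfig,
    seed: int | None = None,
) -> SymptomDiary:
    """Simulate the daily symptom questionnaire for one patient.

    At baseline each count question is positive with probability
    ``symptom_baseline_prob`` (then 1 with probability 0.75, 2 with 0.25) and
    each yes/no question is "yes" with the same probability.  Inside an event
    ramp (onset through hospitalization) each count question is forced to 2
    with probability ``symptom_event_prob`` and each yes/no to "yes"; mood and
    wellbeing drop by ``mood_event_drop`` on the 1-5 Likert scale.
    """
    config.validate()
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else _sub_seed(config.seed, profile.patient_id, 2)
    )
    n = config.duration_days
    days = np.arange(n)
    in_ramp = np.zeros(n, dtype=bool)
    for ev in events:
        in_ramp |= (days >= ev.hospitalization_day - ev.ramp_days) & (
            days <= ev.hospitalization_day
        )

    data: dict[str, np.ndarray] = {"day": days}
    p0 = config.symptom_baseline_prob
    pe = config.symptom_event_prob
    for q in COUNT_QUESTIONS:
        base = np.where(
            rng.random(n) < p0,
            np.where(rng.random(n) < 0.25, 2, 1),
            0,
        ).astype(float)
        escalated = rng.random(n) < pe
        counts = base.copy()
        counts[in_ramp & escalated] = 2.0
        data[q] = counts
    for q in YESNO_QUESTIONS:
        base = (rng.random(n) < p0).astype(float)
        escalated = rng.random(n) < pe
        vals = base.copy()
        vals[in_ramp & escalated] = 1.0
        data[q] = vals

    for col in ("mood", "wellbeing"):
        level = rng.normal(config.mood_baseline, config.mood_sd, n)
        level = level - in_ramp * config.mood_event_drop
        data[col] = np.clip(np.round(level), 1, 5).astype(float)

    frame = pd.DataFrame(data)
    missing = rng.random(n) >= config.compliance
    value_cols = [c for c in frame.columns if c != "day"]
    frame.loc[missing, value_cols] = np.nan
    return SymptomDiary(patient_id=profile.patient_id, data=frame)


@dataclass
class CohortData:
    """Everything the downstream pipeline consumes for one synthetic cohort."""

    config: CohortConfig
    profiles: list[PatientProfile]
    events: list[DecompensationEvent]
    vitals: dict[str, VitalsSeries]
    diaries: dict[str, SymptomDiary]

    def events_for(self, patient_id: str) -> list[DecompensationEvent]:
        return [e for e in self.events if e.patient_id == patient_id]


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Generate the full cohort: profiles, events, vitals and diaries."""
    profiles, events = generate_cohort(config)
    by_pid: dict[str, list[DecompensationEvent]] = {}
    for ev in events:
        by_pid.setdefault(ev.patient_id, []).append(ev)
    vitals = {
        p.patient_id: generate_vitals(p, by_pid.get(p.patient_id, []), config)
        for p in profiles
    }
    diaries = {
        p.patient_id: generate_symptom_diary(p, by_pid.get(p.patient_id, []), config)
        for p in profiles
    }
    return CohortData(config=config, profiles=profiles, events=events,
                      vitals=vitals, diaries=diaries)


# ---------------------------------------------------------------------------
# serialization

_FLOAT_FMT = "%.6g"


def vitals_to_csv(series: Iterable[VitalsSeries], path: str | Path) -> None:
    frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def vitals_from_csv(path: str | Path) -> list[VitalsSeries]:
    frame = pd.read_csv(path)
    return [
        VitalsSeries.from_frame(sub) for _, sub in frame.groupby("patient_id", sort=True)
    ]


def diary_to_csv(diaries: Iterable[SymptomDiary], path: str | Path) -> None:
    frames = []
    for d in diaries:
        f = d.data.copy()
        f.insert(0, "patient_id", d.patient_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def profiles_to_json(profiles: Sequence[PatientProfile], path: str | Path) -> None:
    payload = [asdict(p) for p in profiles]
    for p in payload:
        p["comorbidities"] = list(p["comorbidities"])
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def events_to_json(events: Sequence[DecompensationEvent], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(e) for e in events], indent=1, sort_keys=True))
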