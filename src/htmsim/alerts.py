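"""Deterioration-detection alert algorithms.

Three algorithms turn a patient's daily series into alert days:

* **weight-RoT** — the rule-of-thumb from HF management guidance: alert when
  weight has risen by 2 kg or more over the past 3 days.  Implemented as the
  current weight minus the minimum observed weight on the previous 3 calendar
  days, inclusive of exactly 2.0 kg, so that gaps in the record do not silence
  the rule.
* **weight-MACD** — a trend detector: the difference between a short- and a
  long-horizon exponentially weighted moving average (EWMA) of weight; alert
  when the difference reaches the threshold (default 0.54 kg).
* **impedance-CUSUM** — a one-sided (lower) tabular CUSUM on trans-thoracic
  impedance: each observed value is standardized against the mean and standard
  deviation of a trailing baseline window, and the standardized deviations are
  accumulated; alert when the cumulative sum falls to the threshold (default
  -7).  Fluid accumulation raises tissue conductivity, so impedance *drops*
  ahead of decompensation; weight alerts fire on increases, impedance alerts
  on decreases.

All algorithms operate on observed days only: missing days carry no statistic
and can never be alert days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._errors import ConfigError
from .cohort import VitalsSeries

__all__ = [
    "AlertConfig",
    "AlertSeries",
    "ewma",
    "rot_weight_alerts",
    "macd_weight_alerts",
    "cusum_impedance_alerts",
    "ALGORITHMS",
    "run_algorithm",
]


@dataclass(frozen=True)
class AlertConfig:
    """Thresholds and windows for the three alert algorithms."""

    rot_threshold: float = 2.0  # kg
    rot_lookback: int = 3  # calendar days
    macd_short_span: int = 10  # days
    macd_long_span: int = 30  # days
    macd_threshold: float = 0.54  # kg
    cusum_window: int = 28  # trailing baseline window, observed days
    cusum_slack: float = 0.5  # allowance k per observation
    cusum_threshold: float = -7.0  # alert when C_t <= this
    cusum_sigma_floor: float = 0.5  # ohm
    burn_in: int = 14  # observed days before MACD/CUSUM may alert

    def validate(self) -> None:
        if self.rot_threshold <= 0:
            raise ConfigError("rot_threshold", "must be > 0")
        if self.rot_lookback < 1:
            raise ConfigError("rot_lookback", "must be >= 1")
        if self.macd_short_span >= self.macd_long_span:
            raise ConfigError("macd_short_span", "must be < macd_long_span")
        if self.macd_threshold <= 0:
            raise ConfigError("macd_threshold", "must be > 0")
        if self.cusum_threshold >= 0:
            raise ConfigError("cusum_threshold", "must be < 0")
        if self.cusum_sigma_floor <= 0:
            raise ConfigError("cusum_sigma_floor", "must be > 0")
        if self.cusum_window < 2:
            raise ConfigError("cusum_window", "must be >= 2")
        if self.burn_in < 0:
            raise ConfigError("burn_in", "must be >= 0")


@dataclass
class AlertSeries:
    """Alert days and the per-day detection statistic for one algorithm.

    ``stat_days``/``statistic`` cover the observed days on which the statistic
    is defined; ``alert_days`` is the subset that crossed the threshold.
    """

    patient_id: str
    algorithm: str  # "weight-RoT" | "weight-MACD" | "impedance-CUSUM"
    alert_days: np.ndarray  # int, ordered
    stat_days: np.ndarray  # int, ordered
    statistic: np.ndarray  # same length as stat_days


def ewma(values: np.ndarray, span: int) -> np.ndarray:
    """Exponentially weighted moving average over an ordered observed series.

    s_t = alpha * x_t + (1 - alpha) * s_{t-1} with alpha = 2 / (span + 1),
    initialized at the first observation.  Empty input gives empty output.
    """
    if span < 1:
        raise ConfigError("span", "must be >= 1")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    alpha = 2.0 / (span + 1)
    out = np.empty_like(values)
    out[0] = values[0]
    for t in range(1, len(values)):
        out[t] = alpha * values[t] + (1 - alpha) * out[t - 1]
    return out


def _empty_if_unobserved(series: VitalsSeries, channel: str, algorithm: str):
    days, values = series.observed(channel)
    if days.size == 0:
        warnings.warn(
            f"{series.patient_id}: no observed {channel} values; "
            f"{algorithm} produces no alerts",
            stacklevel=3,
        )
    return days, values


def rot_weight_alerts(series: VitalsSeries, config: AlertConfig | None = None) -> AlertSeries:
    """Weight rule-of-thumb: gain of ``rot_threshold`` kg or more versus the
    minimum observed weight in the previous ``rot_lookback`` calendar days."""
    config = config or AlertConfig()
    config.validate()
    days, weights = _empty_if_unobserved(series, "weight", "weight-RoT")
    day_to_val = dict(zip(days.tolist(), weights.tolist()))
    stat_days, stats, alert_days = [], [], []
    for d, w in zip(days.tolist(), weights.tolist()):
        window = [
            day_to_val[p]
            for p in range(d - config.rot_lookback, d)
            if p in day_to_val
        ]
        if not window:
            continue
        diff = w - min(window)
        stat_days.append(d)
        stats.append(diff)
        if diff >= config.rot_threshold:
            alert_days.append(d)
    return AlertSeries(
        patient_id=series.patient_id,
        algorithm="weight-RoT",
        alert_days=np.asarray(alert_days, dtype=int),
        stat_days=np.asarray(stat_days, dtype=int),
        statistic=np.asarray(stats, dtype=float),
    )


def macd_weight_alerts(series: VitalsSeries, config: AlertConfig | None = None) -> AlertSeries:
    """Weight MACD trend alert: short-span EWMA minus long-span EWMA of the
    observed weights, alert when the difference reaches ``macd_threshold``.

    EWMAs update once per observed measurement; days with no measurement do
    not decay the averages.  The first ``burn_in`` observed days never alert.
    """
    config = config or AlertConfig()
    config.validate()
    days, weights = _empty_if_unobserved(series, "weight", "weight-MACD")
    stat = ewma(weights, config.macd_short_span) - ewma(weights, config.macd_long_span)
    eligible = np.arange(len(days)) >= config.burn_in
    alert_mask = (stat >= config.macd_threshold) & eligible
    return AlertSeries(
        patient_id=series.patient_id,
        algorithm="weight-MACD",
        alert_days=days[alert_mask].astype(int),
        stat_days=days.astype(int),
        statistic=stat,
    )


def cusum_impedance_alerts(series: VitalsSeries, config: AlertConfig | None = None) -> AlertSeries:
    """Lower-sided tabular CUSUM on trans-thoracic impedance.

    For observed day t (index i in observed order, i >= burn_in): the trailing
    ``cusum_window`` observed values ending at i-1 give a baseline mean and sd
    (sd floored at ``cusum_sigma_floor``); z = (x_t - mean) / sd; the statistic
    accumulates C_t = min(0, C_{t-1} + z + k) and alerts when
    C_t <= ``cusum_threshold``.  There is no reset after an alert, so alerts on
    consecutive days are possible (the episode-pruning step relies on this).
    """
    config = config or AlertConfig()
    config.validate()
    days, tti = _empty_if_unobserved(series, "tti", "impedance-CUSUM")
    n = len(days)
    stat_days, stats, alert_days = [], [], []
    c = 0.0
    for i in range(n):
        if i < config.burn_in:
            continue
        lo = max(0, i - config.cusum_window)
        window = tti[lo:i]
        mu = float(np.mean(window))
        sigma = max(float(np.std(window, ddof=1)) if len(window) > 1 else 0.0,
                    config.cusum_sigma_floor)
        z = (tti[i] - mu) / sigma
        c = min(0.0, c + z + config.cusum_slack)
        stat_days.append(int(days[i]))
        stats.append(c)
        if c <= config.cusum_threshold:
            alert_days.append(int(days[i]))
    return AlertSeries(
        patient_id=series.patient_id,
        algorithm="impedance-CUSUM",
        alert_days=np.asarray(alert_days, dtype=int),
        stat_days=np.asarray(stat_days, dtype=int),
        statistic=np.asarray(stats, dtype=float),
    )


ALGORITHMS = {
    "rot": rot_weight_alerts,
    "macd": macd_weight_alerts,
    "cusum": cusum_impedance_alerts,
}


def run_algorithm(name: str, series: VitalsSeries, config: AlertConfig | None = None) -> AlertSeries:
    """Dispatch by short algorithm name ('rot', 'macd', 'cusum')."""
    try:
        fn = ALGORITHMS[name]
    except KeyError:
        raise ConfigError("algorithm", f"unknown algorithm {name!r}") from None
    return fn(series, config)
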