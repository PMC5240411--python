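"""Shared fixtures and independent oracle implementations.

The oracle functions here deliberately re-derive each statistic or alert rule
from its definition (day-by-day loops, explicit pair enumeration) so tests
compare the package against an independent code path.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from htmsim.cohort import VitalsSeries


def make_vitals(
    weight=None,
    tti=None,
    days=None,
    patient_id="T001",
) -> VitalsSeries:
    """Build a VitalsSeries from plain lists; None entries become NaN."""

    def to_arr(values, n):
        if values is None:
            return np.full(n, np.nan)
        return np.array(
            [np.nan if v is None else float(v) for v in values], dtype=float
        )

    n = len(weight) if weight is not None else len(tti)
    day_arr = np.asarray(days if days is not None else np.arange(n), dtype=int)
    return VitalsSeries(
        patient_id=patient_id,
        day=day_arr,
        weight=to_arr(weight, n),
        sbp=np.full(n, 120.0),
        dbp=np.full(n, 75.0),
        hr=np.full(n, 70.0),
        tti=to_arr(tti, n),
    )


@pytest.fixture
def vitals_factory():
    return make_vitals


# ---------------------------------------------------------------------------
# brute-force alert oracles (independent of htmsim.alerts)


def oracle_rot(days, weights, threshold=2.0, lookback=3):
    """Day-by-day evaluation of the weight rule of thumb."""
    observed = {int(d): float(w) for d, w in zip(days, weights) if not math.isnan(w)}
    alerts = []
    for d in sorted(observed):
        prior = [observed[p] for p in range(d - lookback, d) if p in observed]
        if prior and observed[d] - min(prior) >= threshold:
            alerts.append(d)
    return alerts


def oracle_ewma(values, span):
    alpha = 2.0 / (span + 1)
    out = []
    s = None
    for x in values:
        s = x if s is None else alpha * x + (1 - alpha) * s
        out.append(s)
    return out


def oracle_macd(days, weights, short=10, long=30, threshold=0.54, burn_in=14):
    obs = [(int(d), float(w)) for d, w in zip(days, weights) if not math.isnan(w)]
    values = [w for _, w in obs]
    stat = [
        a - b for a, b in zip(oracle_ewma(values, short), oracle_ewma(values, long))
    ]
    return [d for i, (d, _) in enumerate(obs) if i >= burn_in and stat[i] >= threshold]


def oracle_cusum(
    days, tti, window=28, k=0.5, threshold=-7.0, sigma_floor=0.5, burn_in=14
):
    obs = [(int(d), float(x)) for d, x in zip(days, tti) if not math.isnan(x)]
    alerts = []
    c = 0.0
    for i, (d, x) in enumerate(obs):
        if i < burn_in:
            continue
        baseline = [v for _, v in obs[max(0, i - window) : i]]
        mu = sum(baseline) / len(baseline)
        if len(baseline) > 1:
            var = sum((v - mu) ** 2 for v in baseline) / (len(baseline) - 1)
            sigma = max(math.sqrt(var), sigma_floor)
        else:
            sigma = sigma_floor
        c = min(0.0, c + (x - mu) / sigma + k)
        if c <= threshold:
            alerts.append(d)
    return alerts


# ---------------------------------------------------------------------------
# agreement oracles


def oracle_pair_agreement(ratings_by_case):
    """Mean over cases of the fraction of rater pairs that agree.

    ``ratings_by_case``: list of lists of category labels (one inner list per
    case, one label per responding rater).  Explicit enumeration of all pairs.
    """
    per_case = []
    for labels in ratings_by_case:
        pairs = agree = 0
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                pairs += 1
                agree += labels[i] == labels[j]
        if pairs:
            per_case.append(agree / pairs)
    return sum(per_case) / len(per_case)


def oracle_fleiss(counts):
    """Direct textbook evaluation of Fleiss' kappa from a count matrix."""
    counts = np.asarray(counts, dtype=float)
    n_i = counts.sum(axis=1)
    agree = ((counts * (counts - 1)).sum(axis=1) / (n_i * (n_i - 1))).mean()
    p_j = counts.sum(axis=0) / counts.sum()
    p_e = (p_j**2).sum()
    return (agree - p_e) / (1 - p_e)
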