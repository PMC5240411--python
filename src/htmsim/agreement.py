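"""Inter-rater agreement statistics.

Works on a *rating matrix*: one row per case (alert episode), one column per
category, entries counting how many raters assigned that category.  Provides

* raw pairwise agreement — for case i with counts n_ij over n_i raters,
  agree_i = sum_j n_ij (n_ij - 1) / (n_i (n_i - 1)); the statistic is the mean
  of agree_i over cases (the average proportion of agreeing rater-pairs out of
  all possible rater-pairs);
* Fleiss' kappa — chance-corrected multi-rater agreement,
  kappa = (P_bar - P_bar_e) / (1 - P_bar_e) with P_bar the mean per-case
  agreement and P_bar_e = sum_j p_j^2 from the category marginals.  Cases in
  which not every panel member responded are excluded (complete-case rule);
* case-resampling percentile bootstrap confidence intervals for either.

Both statistics share the same per-case agreement kernel, so the P_bar inside
kappa and the raw-agreement statistic agree on identical input by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._errors import ValidationError
from .raters import ACTIONS, RaterResponse

__all__ = [
    "RatingMatrix",
    "AgreementResult",
    "build_matrix",
    "collapse_to_action",
    "raw_agreement",
    "fleiss_kappa",
    "bootstrap_ci",
]

#: Binary category set after pooling the three concern levels.
BINARY_CATEGORIES = ("no_action", "action")


@dataclass
class RatingMatrix:
    """Per-case per-category rater counts."""

    case_ids: list[str]
    categories: tuple[str, ...]
    counts: np.ndarray  # (n_cases, n_categories) int
    panel_size: int  # number of raters in the full panel

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValidationError("rating counts must be non-negative")
        if self.counts.shape != (len(self.case_ids), len(self.categories)):
            raise ValidationError("counts shape does not match cases x categories")

    @property
    def raters_per_case(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def complete(self) -> np.ndarray:
        """True where every panel member rated the case."""
        return self.raters_per_case == self.panel_size

    def subset(self, mask: np.ndarray) -> "RatingMatrix":
        idx = np.flatnonzero(mask)
        return RatingMatrix(
            case_ids=[self.case_ids[i] for i in idx],
            categories=self.categories,
            counts=self.counts[idx],
            panel_size=self.panel_size,
        )


@dataclass
class AgreementResult:
    statistic: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_raters: int
    n_boot: int
    seed: int
    degenerate_resamples: int = 0


def build_matrix(
    responses: Sequence[RaterResponse],
    panel_size: int,
    value: str = "action",
    categories: Sequence[str | int] | None = None,
) -> RatingMatrix:
    """Tabulate responses into a rating matrix.

    ``value`` selects the rated attribute: "action" (4 categories) or
    "rating" (Likert 1-5).
    """
    if categories is None:
        categories = ACTIONS if value == "action" else (1, 2, 3, 4, 5)
    cat_index = {c: k for k, c in enumerate(categories)}
    case_ids = sorted({r.episode_id for r in responses})
    case_index = {c: i for i, c in enumerate(case_ids)}
    counts = np.zeros((len(case_ids), len(categories)), dtype=int)
    for r in responses:
        v = getattr(r, value)
        if v not in cat_index:
            raise ValidationError(f"unknown category label {v!r}")
        counts[case_index[r.episode_id], cat_index[v]] += 1
    return RatingMatrix(
        case_ids=case_ids,
        categories=tuple(str(c) for c in categories),
        counts=counts,
        panel_size=panel_size,
    )


def collapse_to_action(
    responses: Sequence[RaterResponse], panel_size: int
) -> RatingMatrix:
    """Binary matrix pooling beginning / raised / high concern into "action"."""
    matrix = build_matrix(responses, panel_size, value="action")
    no_action = matrix.counts[:, 0]
    action = matrix.counts[:, 1:].sum(axis=1)
    return RatingMatrix(
        case_ids=matrix.case_ids,
        categories=BINARY_CATEGORIES,
        counts=np.column_stack([no_action, action]),
        panel_size=panel_size,
    )


def _per_case_agreement(counts: np.ndarray) -> np.ndarray:
    """agree_i = sum_j n_ij (n_ij - 1) / (n_i (n_i - 1)); requires n_i >= 2."""
    n_i = counts.sum(axis=1)
    num = (counts * (counts - 1)).sum(axis=1)
    return num / (n_i * (n_i - 1))


def raw_agreement(matrix: RatingMatrix, complete_only: bool = False) -> float:
    """Mean over cases of the proportion of agreeing rater pairs.

    Cases with fewer than two raters carry no pair and are excluded (with a
    warning).  ``complete_only`` restricts to complete cases instead.
    """
    mask = matrix.complete if complete_only else matrix.raters_per_case >= 2
    n_dropped = int((~mask & (matrix.raters_per_case < 2)).sum())
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} case(s) with fewer than 2 raters")
    sub = matrix.subset(mask)
    if len(sub.case_ids) == 0:
        raise ValidationError("no cases with >= 2 raters")
    return float(_per_case_agreement(sub.counts).mean())


def fleiss_kappa(matrix: RatingMatrix, complete_only: bool = True) -> float:
    """Fleiss' kappa; by default only complete cases enter (the panel rule).

    Returns NaN (with a warning) when the marginals are degenerate, i.e. a
    single category was used throughout so chance agreement is 1.
    """
    sub = matrix.subset(matrix.complete) if complete_only else matrix.subset(
        matrix.raters_per_case >= 2
    )
    if len(sub.case_ids) == 0:
        raise ValidationError("no eligible cases for kappa")
    p_bar = float(_per_case_agreement(sub.counts).mean())
    totals = sub.counts.sum(axis=0)
    p_j = totals / totals.sum()
    p_e = float((p_j**2).sum())
    if p_e >= 1.0:
        warnings.warn("kappa undefined: a single category was used throughout")
        return float("nan")
    return (p_bar - p_e) / (1.0 - p_e)


def bootstrap_ci(
    matrix: RatingMatrix,
    statistic: Callable[[RatingMatrix], float] | None = None,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> AgreementResult:
    """Percentile bootstrap over cases (rows resampled with replacement).

    Resamples on which the statistic is undefined (NaN) are redrawn; their
    count is reported in the result.  Deterministic for a fixed seed.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    stat_fn = statistic or fleiss_kappa
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = stat_fn(matrix)
    rng = np.random.default_rng(seed)
    n = len(matrix.case_ids)
    values = np.empty(n_boot)
    degenerate = 0
    max_redraws = 100 * n_boot
    for b in range(n_boot):
        while True:
            if degenerate > max_redraws:
                raise ValidationError(
                    "statistic undefined on virtually every resample; "
                    "the data are degenerate for this statistic"
                )
            idx = rng.integers(0, n, size=n)
            sub = RatingMatrix(
                case_ids=[matrix.case_ids[i] for i in idx],
                categories=matrix.categories,
                counts=matrix.counts[idx],
                panel_size=matrix.panel_size,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    v = stat_fn(sub)
                except ValidationError:
                    v = float("nan")
            if np.isnan(v):
                degenerate += 1
                continue
            values[b] = v
            break
    lo, hi = np.quantile(values, [(1 - level) / 2, 1 - (1 - level) / 2])
    return AgreementResult(
        statistic=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_cases=n,
        n_raters=matrix.panel_size,
        n_boot=n_boot,
        seed=seed,
        degenerate_resamples=degenerate,
    )
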