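"""Agreement statistics: raw pairwise agreement, Fleiss kappa, bootstrap CIs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from htmsim._errors import ValidationError
from htmsim.agreement import (
    RatingMatrix,
    bootstrap_ci,
    build_matrix,
    collapse_to_action,
    fleiss_kappa,
    raw_agreement,
)
from htmsim.raters import RaterResponse
from .conftest import oracle_fleiss, oracle_pair_agreement


def matrix(counts, panel_size=None, categories=None):
    counts = np.asarray(counts)
    if categories is None:
        categories = tuple(f"c{j}" for j in range(counts.shape[1]))
    return RatingMatrix(
        case_ids=[f"case{i}" for i in range(counts.shape[0])],
        categories=tuple(categories),
        counts=counts,
        panel_size=panel_size or int(counts.sum(axis=1).max()),
    )


def response(rater, episode, action="no_action", rating=1):
    return RaterResponse(
        rater_id=rater, episode_id=episode, rating=rating,
        called=action != "no_action", action=action, review_time_s=30.0,
    )


class TestCollapse:
    def test_concern_levels_pool_to_action(self):
        responses = [
            response("r1", "e1", "high_concern"),
            response("r2", "e1", "raised_concern"),
            response("r3", "e1", "beginning_concern"),
            response("r4", "e1", "no_action"),
        ]
        m = collapse_to_action(responses, panel_size=4)
        assert m.categories == ("no_action", "action")
        assert m.counts.tolist() == [[1, 3]]

    def test_all_beginning_counts_as_action(self):
        responses = [response(f"r{i}", "e1", "beginning_concern") for i in range(4)]
        m = collapse_to_action(responses, panel_size=4)
        assert m.counts.tolist() == [[0, 4]]

    def test_all_no_action(self):
        responses = [response(f"r{i}", "e1") for i in range(4)]
        m = collapse_to_action(responses, panel_size=4)
        assert m.counts.tolist() == [[4, 0]]

    def test_unknown_category_rejected(self):
        good = response("r1", "e1")
        bad = object.__new__(RaterResponse)
        object.__setattr__(bad, "rater_id", "r2")
        object.__setattr__(bad, "episode_id", "e1")
        object.__setattr__(bad, "rating", 1)
        object.__setattr__(bad, "called", True)
        object.__setattr__(bad, "action", "shrug")
        object.__setattr__(bad, "review_time_s", 30.0)
        with pytest.raises(ValidationError, match="unknown category"):
            collapse_to_action([good, bad], panel_size=2)


class TestRawAgreement:
    def test_perfect_agreement(self):
        assert raw_agreement(matrix([[4, 0], [0, 4]])) == pytest.approx(1.0)

    def test_two_raters_half(self):
        # case 1 agree, case 2 disagree
        assert raw_agreement(matrix([[2, 0], [1, 1]])) == pytest.approx(0.5)

    def test_three_raters_all_different(self):
        assert raw_agreement(matrix([[1, 1, 1]])) == pytest.approx(0.0)

    def test_single_rater_case_excluded_with_warning(self):
        m = matrix([[2, 0], [1, 0]], panel_size=2)
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert raw_agreement(m) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        counts=st.lists(
            st.lists(st.integers(0, 5), min_size=2, max_size=4),
            min_size=1,
            max_size=10,
        )
    )
    def test_matches_pair_enumeration(self, counts):
        counts = [row for row in counts if sum(row) >= 2 and sum(row) <= 5]
        if not counts:
            return
        width = max(len(r) for r in counts)
        counts = [r + [0] * (width - len(r)) for r in counts]
        labels = [
            [cat for cat, n in enumerate(row) for _ in range(n)] for row in counts
        ]
        m = matrix(counts)
        assert raw_agreement(m) == pytest.approx(oracle_pair_agreement(labels))


class TestFleissKappa:
    def test_unanimous_cases_give_one(self):
        assert fleiss_kappa(matrix([[4, 0], [0, 4]])) == pytest.approx(1.0)

    def test_worked_two_case_example(self):
        # P_bar = (1 + 0)/2 = 0.5; p = (0.75, 0.25); P_e = 0.625; kappa = -1/3
        m = matrix([[2, 0], [1, 1]])
        assert fleiss_kappa(m, complete_only=False) == pytest.approx(-1 / 3)

    def test_independent_uniform_ratings_near_zero(self):
        rng = np.random.default_rng(12)
        raters, cases = 4, 5000
        c0 = rng.binomial(raters, 0.5, size=cases)
        m = matrix(np.column_stack([c0, raters - c0]))
        assert abs(fleiss_kappa(m)) < 0.02

    def test_matches_direct_formula_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = rng.multinomial(5, [0.5, 0.3, 0.2], size=12)
            assert fleiss_kappa(matrix(counts)) == pytest.approx(
                oracle_fleiss(counts)
            )

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(21)
        counts = rng.multinomial(6, [0.6, 0.4], size=30)
        assert fleiss_kappa(matrix(counts)) == pytest.approx(
            sm_fleiss(counts), abs=1e-12
        )

    def test_complete_case_rule(self):
        # second case has only 3 of 4 raters and must be excluded
        m = matrix([[4, 0], [2, 1], [0, 4]], panel_size=4)
        assert fleiss_kappa(m) == pytest.approx(
            fleiss_kappa(matrix([[4, 0], [0, 4]], panel_size=4))
        )

    def test_degenerate_single_category(self):
        with pytest.warns(UserWarning, match="single category"):
            assert np.isnan(fleiss_kappa(matrix([[4, 0], [4, 0]])))

    def test_kappa_at_most_one(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.multinomial(4, [0.4, 0.4, 0.2], size=8)
            k = fleiss_kappa(matrix(counts))
            if not np.isnan(k):
                assert k <= 1.0 + 1e-12

    def test_invariance_to_case_and_category_permutation(self):
        rng = np.random.default_rng(9)
        counts = rng.multinomial(5, [0.5, 0.3, 0.2], size=15)
        base = fleiss_kappa(matrix(counts))
        assert fleiss_kappa(matrix(counts[::-1])) == pytest.approx(base)
        assert fleiss_kappa(matrix(counts[:, ::-1])) == pytest.approx(base)

    def test_shared_kernel_with_raw_agreement(self):
        """The mean per-case agreement inside kappa equals raw_agreement:
        recovering P_bar from kappa reproduces the raw statistic."""
        rng = np.random.default_rng(4)
        counts = rng.multinomial(4, [0.55, 0.45], size=25)
        m = matrix(counts)
        p_bar = raw_agreement(m)
        p_j = counts.sum(axis=0) / counts.sum()
        p_e = float((p_j**2).sum())
        assert fleiss_kappa(m) == pytest.approx((p_bar - p_e) / (1 - p_e))


class TestBootstrap:
    def test_identical_cases_zero_width(self):
        m = matrix([[3, 1]] * 10)
        res = bootstrap_ci(m, raw_agreement, n_boot=200, seed=1)
        assert res.ci_low == res.ci_high == pytest.approx(res.statistic)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        m = matrix(rng.multinomial(4, [0.6, 0.4], size=40))
        a = bootstrap_ci(m, fleiss_kappa, n_boot=300, seed=5)
        b = bootstrap_ci(m, fleiss_kappa, n_boot=300, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        m = matrix(rng.multinomial(4, [0.6, 0.4], size=60))
        res = bootstrap_ci(m, fleiss_kappa, n_boot=500, seed=7)
        assert res.ci_low <= res.statistic <= res.ci_high

    def test_degenerate_resamples_redrawn(self):
        # one mixed case among unanimous-single-category cases: resamples
        # without it are degenerate and must be redrawn
        m = matrix([[4, 0]] * 6 + [[2, 2]])
        res = bootstrap_ci(m, fleiss_kappa, n_boot=150, seed=11)
        assert res.degenerate_resamples > 0
        assert np.isfinite(res.ci_low) and np.isfinite(res.ci_high)

    def test_n_boot_floor(self):
        with pytest.raises(ValidationError, match="n_boot"):
            bootstrap_ci(matrix([[2, 2]]), fleiss_kappa, n_boot=10, seed=0)


class TestBuildMatrix:
    def test_rating_matrix_five_categories(self):
        responses = [
            response("r1", "e1", "no_action", rating=2),
            response("r2", "e1", "no_action", rating=2),
            response("r1", "e2", "no_action", rating=5),
        ]
        m = build_matrix(responses, panel_size=2, value="rating")
        assert m.counts.shape == (2, 5)
        assert m.counts[0].tolist() == [0, 2, 0, 0, 0]
        assert m.complete.tolist() == [True, False]
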