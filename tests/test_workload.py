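"""Workload analyses: capping, imputation, review-time totals, Mann-Whitney,
rating/action tabulations, sensitivity and composites."""

import math

import numpy as np
import pandas as pd
import pytest

from htmsim._errors import ValidationError
from htmsim.alerts import AlertSeries
from htmsim.cohort import DecompensationEvent
from htmsim.episodes import Episode
from htmsim.raters import RaterResponse
from htmsim.workload import (
    action_by_outcome,
    algorithm_sensitivity,
    cap_and_impute_times,
    detection_weighted_action_rate,
    mann_whitney_u,
    rating_distribution,
    total_review_time,
)


def response(rater, episode, time_s=30.0, action="no_action", rating=3):
    return RaterResponse(
        rater_id=rater, episode_id=episode, rating=rating,
        called=action != "no_action", action=action, review_time_s=time_s,
    )


class TestCapAndImpute:
    def test_above_cap_truncated(self):
        frame = cap_and_impute_times([response("r1", "e1", 400.0)], ["r1"])
        assert frame["review_time_s"].tolist() == [300.0]

    def test_below_cap_unchanged(self):
        responses = [response("r1", "e1", 120.0), response("r1", "e2", 299.0)]
        frame = cap_and_impute_times(responses, ["r1"])
        assert sorted(frame["review_time_s"]) == [120.0, 299.0]

    def test_missing_rater_imputed_with_episode_mean(self):
        responses = [response("r1", "e1", 60.0), response("r2", "e1", 120.0)]
        frame = cap_and_impute_times(responses, ["r1", "r2", "r3"])
        imputed = frame[frame["imputed"]]
        assert imputed["rater_id"].tolist() == ["r3"]
        assert imputed["review_time_s"].iloc[0] == pytest.approx(90.0)

    def test_imputation_uses_capped_times(self):
        responses = [response("r1", "e1", 600.0), response("r2", "e1", 100.0)]
        frame = cap_and_impute_times(responses, ["r1", "r2", "r3"])
        imputed = frame[frame["imputed"]]["review_time_s"].iloc[0]
        assert imputed == pytest.approx((300.0 + 100.0) / 2)

    def test_capping_never_increases_and_is_monotone_in_cap(self):
        rng = np.random.default_rng(1)
        responses = [
            response(f"r{i % 3}", f"e{i}", float(t))
            for i, t in enumerate(rng.lognormal(4.0, 1.0, 60))
        ]
        raw_total = sum(r.review_time_s for r in responses)
        totals = []
        for cap in (60.0, 300.0, 1e9):
            frame = cap_and_impute_times(responses, ["r0", "r1", "r2"], cap_s=cap)
            own = frame[~frame["imputed"]]["review_time_s"].sum()
            assert own <= raw_total + 1e-9
            totals.append(own)
        assert totals[0] <= totals[1] <= totals[2]

    def test_no_responses_at_all_warns(self):
        with pytest.warns(UserWarning, match="no responses"):
            frame = cap_and_impute_times([], ["r1"])
        assert frame.empty


class TestTotalReviewTime:
    def test_300_alerts_at_30s_is_150_minutes(self):
        responses = [response("r1", f"e{i}", 30.0) for i in range(300)]
        frame = cap_and_impute_times(responses, ["r1"])
        assert total_review_time(frame, "r1") == pytest.approx(150.0)

    def test_empty_is_zero(self):
        frame = pd.DataFrame(columns=["rater_id", "episode_id", "review_time_s"])
        assert total_review_time(frame, "r1") == 0.0

    def test_equals_brute_force_sum(self):
        rng = np.random.default_rng(2)
        responses = [
            response(f"r{i % 4}", f"e{i}", float(t))
            for i, t in enumerate(rng.lognormal(3.3, 0.5, 200))
        ]
        frame = cap_and_impute_times(responses, [f"r{k}" for k in range(4)])
        for k in range(4):
            expected = sum(
                min(r.review_time_s, 300.0)
                for r in responses
                if r.rater_id == f"r{k}"
            )
            # each rater responded to their own episodes only, so the other
            # raters' rows for those episodes are imputed copies
            own = frame[(frame["rater_id"] == f"r{k}") & (~frame["imputed"])]
            assert own["review_time_s"].sum() == pytest.approx(expected)


class TestMannWhitney:
    def test_identical_samples_centre_u_and_p_near_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(a, a)
        assert u == pytest.approx(len(a) * len(a) / 2)
        assert p > 0.9

    def test_complete_separation_exact_p(self):
        a = list(range(1, 9))
        b = list(range(100, 108))
        _, p = mann_whitney_u([float(x) for x in a], [float(x) for x in b])
        assert p == pytest.approx(2 / math.comb(16, 8), rel=1e-9)

    def test_exact_vs_asymptotic_within_ten_percent_at_n12(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.8, 1.0, 12)
        _, p_exact = mann_whitney_u(a, b)  # n<=12, no ties -> exact branch
        from scipy import stats

        p_approx = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert abs(p_exact - p_approx) / p_exact < 0.10

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestRatingDistribution:
    def test_single_rater_all_threes(self):
        responses = [response("r1", f"e{i}", rating=3) for i in range(10)]
        table = rating_distribution(responses)
        assert table.loc["r1"].tolist() == [0, 0, 1.0, 0, 0]

    def test_rows_sum_to_one_and_match_tabulation(self):
        rng = np.random.default_rng(3)
        responses = [
            response(f"r{i % 5}", f"e{i}", rating=int(r))
            for i, r in enumerate(rng.integers(1, 6, 400))
        ]
        table = rating_distribution(responses)
        raters = [f"r{k}" for k in range(5)]
        for rater in raters:
            row = table.loc[rater]
            assert row.sum() == pytest.approx(1.0)
            own = [r.rating for r in responses if r.rater_id == rater]
            for rating in range(1, 6):
                assert row[rating] == pytest.approx(
                    own.count(rating) / len(own)
                )
        np.testing.assert_allclose(
            table.loc["se"].to_numpy(), table.loc["sd"].to_numpy() / np.sqrt(5)
        )


class TestActionByOutcome:
    def episodes(self):
        return [
            Episode(episode_id="e1", patient_id="p1", end_day=40, decompensated=True),
            Episode(episode_id="e2", patient_id="p2", end_day=50, decompensated=False),
        ]

    def test_stratified_rates(self):
        responses = [
            response("r1", "e1", action="high_concern"),
            response("r2", "e1", action="beginning_concern"),
            response("r1", "e2", action="no_action"),
            response("r2", "e2", action="raised_concern"),
        ]
        split = action_by_outcome(responses, self.episodes())
        assert split.concern_rate_decomp == pytest.approx(0.5)  # high yes, beginning no
        assert split.concern_rate_no_decomp == pytest.approx(0.5)
        assert split.n_decomp == 2 and split.n_no_decomp == 2

    def test_empty_stratum_flagged(self):
        responses = [response("r1", "e2")]
        with pytest.warns(UserWarning, match="decompensated=True"):
            split = action_by_outcome(responses, self.episodes())
        assert math.isnan(split.concern_rate_decomp)

    def test_unlabeled_episode_rejected(self):
        eps = [Episode(episode_id="e1", patient_id="p1", end_day=40)]
        with pytest.raises(ValidationError, match="unlabeled"):
            action_by_outcome([response("r1", "e1")], eps)


class TestSensitivity:
    def event(self, pid, hosp):
        return DecompensationEvent(
            patient_id=pid, onset_day=hosp - 14, hospitalization_day=hosp,
            weight_gain_total=3.0, impedance_drop_total=5.0, ramp_days=14,
        )

    def alerts(self, pid, days):
        arr = np.asarray(days, dtype=int)
        return AlertSeries(pid, "weight-RoT", arr, arr, np.zeros(len(arr)))

    def test_all_events_preceded(self):
        alerts = {"p1": self.alerts("p1", [45]), "p2": self.alerts("p2", [90])}
        events = [self.event("p1", 50), self.event("p2", 100)]
        assert algorithm_sensitivity(alerts, events) == 1.0

    def test_no_alerts(self):
        alerts = {"p1": self.alerts("p1", [])}
        assert algorithm_sensitivity(alerts, [self.event("p1", 50)]) == 0.0

    def test_window_boundaries(self):
        # alert on hospitalization day itself does not count; 28 days before does
        events = [self.event("p1", 50)]
        assert algorithm_sensitivity({"p1": self.alerts("p1", [50])}, events) == 0.0
        assert algorithm_sensitivity({"p1": self.alerts("p1", [22])}, events) == 1.0
        assert algorithm_sensitivity({"p1": self.alerts("p1", [21])}, events) == 0.0

    def test_no_events_flagged(self):
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            assert math.isnan(algorithm_sensitivity({}, []))


class TestComposite:
    def test_product(self):
        assert detection_weighted_action_rate(0.60, 0.470) == pytest.approx(0.282)

    def test_edges(self):
        assert detection_weighted_action_rate(0.0, 0.9) == 0.0
        assert detection_weighted_action_rate(1.0, 1.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="sensitivity"):
            detection_weighted_action_rate(1.2, 0.5)
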