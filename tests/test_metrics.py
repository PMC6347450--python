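"""Coordination metrics: variance, non-contributors, ICC, decision times,
contest outcomes, smoothing and the bootstrap cloud."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iadc import metrics as m
from oracles import anova_icc1


class TestWithinGroupVariance:
    @pytest.mark.parametrize(
        "triple, expected", [((5, 5, 5), 0.0), ((0, 10, 20), 100.0)]
    )
    def test_closed_forms(self, triple, expected):
        assert m.within_group_variance(triple) == pytest.approx(expected)

    @given(st.tuples(*[st.integers(0, 20)] * 3))
    @settings(max_examples=100, deadline=None)
    def test_matches_two_pass_formula_and_permutation_invariance(self, t):
        mean = sum(t) / 3
        ref = sum((x - mean) ** 2 for x in t) / 2
        assert m.within_group_variance(t) == pytest.approx(ref)
        assert m.within_group_variance(t[::-1]) == pytest.approx(ref)
        if ref == 0:
            assert len(set(t)) == 1

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            m.within_group_variance([1, 2])


class TestNoncontributors:
    def _block(self, contribs):
        rounds = np.repeat(np.arange(1, len(contribs) // 3 + 1), 3)
        return pd.DataFrame({"round": rounds, "contribution": contribs})

    def test_all_zero_block_is_45(self):
        blk = self._block([0] * 45)
        out = m.count_noncontributors(blk)
        assert out["total"] == 45
        assert (out["per_round"] == 3).all()

    def test_all_positive_is_zero(self):
        assert m.count_noncontributors(self._block([5] * 45))["total"] == 0

    def test_mixed_fixture_hand_count(self):
        contribs = [0, 5, 0, 1, 0, 2, 0, 0, 0]  # rounds: 2, 1, 3 zeros
        out = m.count_noncontributors(self._block(contribs))
        assert out["total"] == 6
        assert out["per_round"].tolist() == [2, 1, 3]


class TestICC:
    def test_internally_constant_groups_give_one(self):
        x = np.array([[3.0, 3.0, 3.0], [7.0, 7.0, 7.0], [1.0, 1.0, 1.0]])
        assert m.icc_group_cohesion(x) == pytest.approx(1.0)

    def test_two_group_fixture_matches_manual_anova(self):
        x = np.array([[1.0, 3.0], [2.0, 6.0]])
        assert m.icc_group_cohesion(x) == pytest.approx(anova_icc1(x))

    def test_random_tables_match_manual_anova(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=(6, 9))
            assert m.icc_group_cohesion(x) == pytest.approx(anova_icc1(x))

    def test_null_distribution_centers_on_zero(self):
        rng = np.random.default_rng(11)
        vals = [
            m.icc_group_cohesion(rng.normal(size=(10, 8))) for _ in range(400)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=(4, 6))
            icc = m.icc_group_cohesion(x)
            assert -1 / 5 - 1e-9 <= icc <= 1 + 1e-9

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="single group"):
            m.icc_group_cohesion(np.ones((1, 5)))


class TestDecisionTimes:
    def test_cutoff_log_and_fraction(self):
        n = 200
        df = pd.DataFrame(
            {
                "decision_time_s": [100.0] * (n - 1) + [181.0],
                "contribution": [0, 5] * (n // 2),
            }
        )
        out = m.preprocess_decision_times(df)
        assert len(out) == n - 1
        assert out["log10_time"].iloc[0] == pytest.approx(2.0)
        assert out.attrs["excluded_fraction"] == pytest.approx(0.005)
        assert out["contributed"].tolist() == [False, True] * (n // 2 - 1) + [False]

    def test_exactly_180_is_kept(self):
        df = pd.DataFrame({"decision_time_s": [180.0], "contribution": [1]})
        assert len(m.preprocess_decision_times(df)) == 1

    def test_nonpositive_times_excluded(self):
        df = pd.DataFrame({"decision_time_s": [0.0, 10.0], "contribution": [1, 1]})
        out = m.preprocess_decision_times(df)
        assert len(out) == 1
        assert out.attrs["excluded_fraction"] == pytest.approx(0.5)


class TestContestOutcomes:
    def test_winless_group_has_missing_spoils(self):
        out = m.contest_outcomes(
            np.array([5, 6]), np.array([10, 6]), np.array([[2, 2, 1], [2, 2, 2]])
        )
        assert out.success_rate == 0.0
        assert np.isnan(out.mean_spoils_win)
        assert out.mean_leftover_loss == pytest.approx(20 - 11 / 6)

    def test_sweep_of_defenseless_rival(self):
        out = m.contest_outcomes(
            np.array([10, 12]), np.array([0, 0]), np.array([[4, 3, 3], [4, 4, 4]])
        )
        assert out.success_rate == 1.0
        assert out.mean_spoils_win == pytest.approx(20.0)  # 60/3
        assert np.isnan(out.mean_leftover_loss)

    def test_mixed_fixture_enumeration(self):
        ga = np.array([10, 3, 30])
        gd = np.array([5, 9, 30])           # wins: round 0 only (tie loses)
        a = np.array([[4, 4, 2], [1, 1, 1], [10, 10, 10]])
        out = m.contest_outcomes(ga, gd, a)
        assert out.success_rate == pytest.approx(1 / 3)
        assert out.mean_spoils_win == pytest.approx((60 - 5) / 3)
        leftovers = (20 - a[[1, 2]]).mean()
        assert out.mean_leftover_loss == pytest.approx(leftovers)
        assert out.success_rate * out.n_rounds == pytest.approx(1.0)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        x = np.full(15, 4.2)
        assert m.moving_average(x) == pytest.approx(x)

    def test_small_example(self):
        out = m.moving_average([0.0, 3.0, 6.0], window=3)
        assert out[1] == pytest.approx(3.0)
        assert out[0] == pytest.approx(1.5)   # shrinking edge window
        assert out[2] == pytest.approx(4.5)

    def test_interior_matches_convolution(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        out = m.moving_average(x, window=3)
        ref = np.convolve(x, np.ones(3) / 3, mode="valid")
        assert out[1:-1] == pytest.approx(ref)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            m.moving_average([])


class TestBootstrapCloud:
    def test_single_group_condition_collapses(self):
        df = m.bootstrap_bivariate_means(
            np.array([4.0]), np.array([22.0]), np.array(["a"]), n_boot=50
        )
        assert (df["mean_contribution"] == 4.0).all()
        assert (df["mean_payment"] == 22.0).all()

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        c = rng.normal(6, 2, 40)
        p = rng.normal(20, 3, 40)
        cond = np.repeat(["a", "b"], 20)
        d1 = m.bootstrap_bivariate_means(c, p, cond, seed=7)
        d2 = m.bootstrap_bivariate_means(c, p, cond, seed=7)
        pd.testing.assert_frame_equal(d1, d2)

    def test_centroid_near_condition_mean(self):
        rng = np.random.default_rng(2)
        c = rng.normal(6, 2, 80)
        p = rng.normal(20, 3, 80)
        cond = np.repeat(["a", "b"], 40)
        cloud = m.bootstrap_bivariate_means(c, p, cond, n_boot=2000, seed=0)
        for lab in ("a", "b"):
            mask = cond == lab
            sub = cloud[cloud.condition == lab]
            se = c[mask].std() / np.sqrt(40)
            assert abs(sub["mean_contribution"].mean() - c[mask].mean()) < 3 * se

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            m.bootstrap_bivariate_means(
                np.array([]), np.array([]), np.array([]), n_boot=10
            )
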