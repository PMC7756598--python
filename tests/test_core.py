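"""Unit and property tests for the weighted directional-prediction test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

import predtest as pt
from predtest.core import _subset_sums


def random_corr(rng, m):
    return pt.random_correlation(m, rng=rng)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

class TestComputeWeights:
    def test_identity_gives_unit_weights(self):
        w = pt.compute_weights(np.eye(3))
        assert np.allclose(w.w, 1.0)
        assert w.W == pytest.approx(3.0)

    def test_all_ones_gives_reciprocal_m(self):
        w = pt.compute_weights(np.ones((4, 4)))
        assert np.allclose(w.w, 0.25)
        assert w.W == pytest.approx(1.0)

    def test_two_endpoints_hand_computed(self):
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        w = pt.compute_weights(C)
        assert np.allclose(w.w, 1 / 1.36)
        assert w.W == pytest.approx(2 / 1.36)

    @pytest.mark.parametrize(
        "bad, match",
        [
            (np.ones((2, 3)), "square"),
            (np.array([[1.0, 0.5], [0.2, 1.0]]), "not symmetric"),
            (np.array([[1.0, 1.2], [1.2, 1.0]]), "outside"),
            (np.array([[0.9, 0.1], [0.1, 1.0]]), "diagonal"),
            (np.array([[1.0]]), "at least 2"),
        ],
    )
    def test_invalid_matrices_rejected(self, bad, match):
        with pytest.raises(ValueError, match=match):
            pt.compute_weights(bad)

    def test_non_psd_rejected(self):
        C = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            pt.compute_weights(C)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(m=st.integers(2, 12), seed=st.integers(0, 2**31 - 1))
    def test_weight_bounds_for_random_matrices(self, m, seed):
        """Each w_i is in [1/m, 1] and W in [1, m] for any valid C."""
        C = random_corr(np.random.default_rng(seed), m)
        w = pt.compute_weights(C)
        assert np.all(w.w >= 1 / m - 1e-12)
        assert np.all(w.w <= 1 + 1e-12)
        assert 1 - 1e-9 <= w.W <= m + 1e-9


# ---------------------------------------------------------------------------
# prediction outcomes and statistic
# ---------------------------------------------------------------------------

class TestEvaluatePredictions:
    def test_asl_effect_signs(self, asl):
        out = pt.evaluate_predictions(asl["mean_differences"], asl["predictions"])
        assert out.p.tolist() == [1, 1, 0, 1, 1, 0]
        assert out.n_correct == 4

    def test_all_wrong_directions(self):
        out = pt.evaluate_predictions([-1.0, -2.0, -0.5], [1, 1, 1])
        assert out.p.tolist() == [0, 0, 0]

    def test_exact_zero_effect_counts_as_incorrect(self):
        assert pt.evaluate_predictions([0.0], [1]).p.tolist() == [0]
        assert pt.evaluate_predictions([0.0], [-1]).p.tolist() == [0]

    def test_length_mismatch_and_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="predictions"):
            pt.evaluate_predictions([1.0, 2.0], [1])
        with pytest.raises(ValueError, match="finite"):
            pt.evaluate_predictions([np.nan], [1])

    def test_direction_tokens(self):
        preds = pt.DirectionPredictions(np.array(["up", "down", "+1"]))
        assert preds.signs.tolist() == [1, -1, 1]
        with pytest.raises(ValueError, match="direction"):
            pt.DirectionPredictions(np.array(["sideways"]))


class TestTestStatistic:
    def test_worked_example_equals_1_74(self, asl):
        t = pt.test_statistic(asl["outcomes"], asl["weights"])
        assert t == pytest.approx(1.74, abs=1e-12)

    def test_extremes(self):
        w = pt.WeightVector(np.ones(5))
        assert pt.test_statistic(np.zeros(5, dtype=int), w) == 0.0
        assert pt.test_statistic(np.ones(5, dtype=int), w) == 5.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="weights"):
            pt.test_statistic([1, 0], [0.5, 0.5, 0.5])


# ---------------------------------------------------------------------------
# exact null distribution
# ---------------------------------------------------------------------------

class TestExactNullDistribution:
    def test_equal_weight_vectors_are_equiprobable(self):
        """m = 6, phi0 = 0.5: every one of the 64 prediction vectors has
        probability 1/64 = 0.015625."""
        vals, k = _subset_sums(np.full(6, 1 / 6))
        dist = pt.exact_null_distribution(np.full(6, 1 / 6), 0.5)
        assert np.allclose(
            dist.probs, binom.pmf(np.arange(7), 6, 0.5)
        )
        # each underlying vector carries 0.5**6
        assert dist.probs[0] == pytest.approx(0.015625)
        assert dist.probs[3] == pytest.approx(0.3125)

    def test_identity_reduces_to_binomial(self):
        dist = pt.exact_null_distribution(np.ones(7), 0.3)
        assert np.allclose(dist.support, np.arange(8))
        assert np.allclose(dist.probs, binom.pmf(np.arange(8), 7, 0.3))

    def test_perfect_dependence_is_scaled_binomial(self):
        m = 5
        w = pt.compute_weights(np.ones((m, m)))
        dist = pt.exact_null_distribution(w, 0.6)
        assert np.allclose(dist.support, np.arange(m + 1) / m)
        assert np.allclose(dist.probs, binom.pmf(np.arange(m + 1), m, 0.6))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        m=st.integers(2, 10),
        phi0=st.floats(0.05, 0.95),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_conservation_mean_and_variance(self, m, phi0, seed):
        """Probabilities sum to 1; mean = phi0*W and var = phi0(1-phi0)*sum w^2
        to 1e-10, for random correlation structures."""
        w = pt.compute_weights(random_corr(np.random.default_rng(seed), m))
        dist = pt.exact_null_distribution(w, phi0)
        assert abs(dist.probs.sum() - 1.0) < 1e-12
        assert abs(dist.mean - phi0 * w.W) < 1e-10
        assert abs(dist.var - phi0 * (1 - phi0) * w.sumsq) < 1e-10
        assert dist.support[0] >= -1e-12
        assert dist.support[-1] <= w.W + 1e-12

    def test_enumeration_cap(self):
        with pytest.raises(ValueError, match="normal approximation"):
            pt.exact_null_distribution(np.ones(26), 0.5)


class TestExactPvalue:
    def test_zero_statistic_has_pvalue_one(self, rng):
        w = pt.compute_weights(random_corr(rng, 5))
        dist = pt.exact_null_distribution(w, 0.5)
        assert pt.exact_pvalue(0.0, dist) == pytest.approx(1.0)

    def test_perfect_record_matches_binomial_tail(self):
        dist = pt.exact_null_distribution(np.ones(5), 0.5)
        assert pt.exact_pvalue(5.0, dist) == pytest.approx(0.5 ** 5)

    def test_asl_printed_weights_tail_is_19_of_64(self, asl):
        """Brute-force enumeration over all 64 vectors: 19 reach 1.74."""
        dist = pt.exact_null_distribution(asl["weights"], 0.5)
        assert pt.exact_pvalue(1.74, dist) == pytest.approx(19 / 64)

    def test_tail_helper_matches_distribution_route(self, rng):
        for m in (3, 6, 11):
            w = pt.compute_weights(random_corr(rng, m))
            dist = pt.exact_null_distribution(w, 0.37)
            for t in np.linspace(-0.5, w.W + 0.5, 23):
                assert pt.exact_tail_probability(t, w, 0.37) == pytest.approx(
                    pt.exact_pvalue(t, dist), abs=1e-12
                )

    def test_identity_pvalue_equals_binomial_tail(self, rng):
        m, phi0 = 9, 0.65
        w = pt.compute_weights(np.eye(m))
        dist = pt.exact_null_distribution(w, phi0)
        for k in range(m + 1):
            assert pt.exact_pvalue(float(k), dist) == pytest.approx(
                binom.sf(k - 1, m, phi0), abs=1e-12
            )

    def test_monte_carlo_oracle(self, rng):
        """Exact p-value agrees with a 200,000-draw Bernoulli simulation
        within 3 Monte-Carlo standard errors, for random weights and phi0."""
        n_draws = 200_000
        for m, phi0 in [(4, 0.5), (8, 0.3), (12, 0.7)]:
            w = pt.compute_weights(random_corr(rng, m))
            t_obs = 0.6 * w.W
            P = (rng.random((n_draws, m)) < phi0).astype(float)
            stats = P @ w.w
            mc = float((stats >= t_obs - 1e-9).mean())
            se = np.sqrt(max(mc * (1 - mc), 1e-12) / n_draws)
            exact = pt.exact_tail_probability(t_obs, w, phi0)
            assert abs(exact - mc) <= 3 * se + 1e-12

    def test_monotone_nonincreasing_in_t(self, rng):
        w = pt.compute_weights(random_corr(rng, 8))
        dist = pt.exact_null_distribution(w, 0.45)
        ts = np.linspace(0, w.W, 60)
        pv = [pt.exact_pvalue(t, dist) for t in ts]
        assert np.all(np.diff(pv) <= 1e-12)


class TestNormalPvalue:
    def test_half_at_the_mean(self, rng):
        w = pt.compute_weights(random_corr(rng, 10))
        assert pt.normal_pvalue(0.5 * w.W, w, 0.5) == pytest.approx(0.5)

    def test_standard_quantile(self, rng):
        w = pt.compute_weights(random_corr(rng, 10))
        phi0 = 0.5
        mu = phi0 * w.W
        sigma = np.sqrt(phi0 * (1 - phi0) * w.sumsq)
        assert pt.normal_pvalue(mu + 1.6448536269514722 * sigma, w, phi0) == (
            pytest.approx(0.05, abs=1e-9)
        )

    def test_strictly_decreasing_in_t(self, rng):
        w = pt.compute_weights(random_corr(rng, 15))
        ts = np.linspace(0, w.W, 40)
        pv = [pt.normal_pvalue(t, w, 0.5) for t in ts]
        assert np.all(np.diff(pv) < 0)


# ---------------------------------------------------------------------------
# feasibility rule
# ---------------------------------------------------------------------------

class TestMinimumRequiredM:
    @pytest.mark.parametrize(
        "phi0, expected", [(0.5, 5), (0.6, 6), (0.7, 9), (0.9, 29)]
    )
    def test_published_feasibility_entries(self, phi0, expected):
        assert pt.minimum_required_m(phi0, 0.05) == expected

    def test_rule_gives_14_for_phi0_080(self):
        """0.8**13 = 0.0550 > 0.05 but 0.8**14 = 0.0440 <= 0.05."""
        assert pt.minimum_required_m(0.8, 0.05) == 14

    def test_boundary_equality_counts(self):
        assert pt.minimum_required_m(0.5, 0.0625) == 4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pt.minimum_required_m(1.0, 0.05)
        with pytest.raises(ValueError):
            pt.minimum_required_m(0.5, 0.0)


# ---------------------------------------------------------------------------
# full test pipeline
# ---------------------------------------------------------------------------

class TestRunPredictionTest:
    def test_worked_example_fails_to_reject(self, asl):
        res = pt.prediction_test(asl["outcomes"], asl["weights"],
                                 phi0=0.5, alpha=0.05)
        assert res.statistic == pytest.approx(1.74)
        assert res.method == "exact"
        assert not res.reject
        assert res.p_value > 0.05

    def test_gate_blocks_small_statistic(self):
        """p <= alpha but T_m < 1 with the gate on: no rejection."""
        w = pt.WeightVector(np.full(4, 0.25))  # perfect dependence, W = 1
        p = pt.PredictionOutcomes(np.array([1, 1, 1, 0]))  # T = 0.75
        res = pt.prediction_test(p, w, phi0=0.05, alpha=0.05)
        assert res.p_value <= 0.05
        assert res.statistic < 1
        assert not res.reject
        res_no_gate = pt.prediction_test(
            p, w, phi0=0.05, alpha=0.05, require_T_ge_1=False
        )
        assert res_no_gate.reject

    def test_perfect_dependence_requires_all_correct(self):
        """With C = J any single wrong prediction makes T_m < 1."""
        C = np.ones((6, 6))
        out = np.array([1, 1, 1, 1, 1, 0])
        res = pt.run_prediction_test(correlation=C, outcomes=out, phi0=0.5)
        assert res.statistic < 1
        assert not res.reject
        res_all = pt.run_prediction_test(
            correlation=C, outcomes=np.ones(6, dtype=int), phi0=0.5
        )
        assert res_all.statistic == pytest.approx(1.0)
        assert res_all.reject  # p = 0.5**6 < 0.05 and T_m >= 1

    def test_auto_method_switch(self, rng):
        C = random_corr(rng, 4)
        out = np.array([1, 1, 0, 1])
        assert pt.run_prediction_test(
            correlation=C, outcomes=out).method == "exact"
        assert pt.run_prediction_test(
            correlation=C, outcomes=out, exact_limit=3).method == "normal"
        C_big = random_corr(rng, 22)
        res = pt.run_prediction_test(
            correlation=C_big, outcomes=np.ones(22, dtype=int)
        )
        assert res.method == "normal"

    def test_exact_and_normal_agree_for_moderate_m(self, rng):
        C = random_corr(rng, 18)
        out = (rng.random(18) < 0.7).astype(int)
        r_exact = pt.run_prediction_test(
            correlation=C, outcomes=out, method="exact")
        r_norm = pt.run_prediction_test(
            correlation=C, outcomes=out, method="normal")
        assert r_exact.p_value == pytest.approx(r_norm.p_value, abs=0.05)

    def test_single_endpoint_rejected(self):
        with pytest.raises(ValueError, match="multiple-endpoint"):
            pt.run_prediction_test(correlation=np.eye(1), outcomes=[1])

    def test_invalid_phi0_and_alpha(self, rng):
        C = random_corr(rng, 3)
        with pytest.raises(ValueError, match="phi0"):
            pt.run_prediction_test(correlation=C, outcomes=[1, 1, 1], phi0=1.5)
        with pytest.raises(ValueError, match="alpha"):
            pt.run_prediction_test(correlation=C, outcomes=[1, 1, 1], alpha=0.0)

    def test_data_pipeline_paired_matches_manual(self, rng):
        import pandas as pd

        C = random_corr(rng, 5)
        df = pt.make_dataset(C, "stagger", 30, design="paired", rng=rng)
        preds = np.array([1, 1, 1, -1, 1])
        res = pt.run_prediction_test(df, preds, "paired")
        effects = df.to_numpy().mean(axis=0)
        w = pt.compute_weights(np.corrcoef(df.to_numpy(), rowvar=False))
        out = pt.evaluate_predictions(effects, preds)
        assert res.statistic == pytest.approx(pt.test_statistic(out, w))

    def test_two_group_weights_use_pooled_within_group_correlation(self, rng):
        """A large between-group shift must not contaminate the weights."""
        C = np.eye(3)
        df = pt.make_dataset(C, np.array([10.0, 10.0, 10.0]), 200,
                             design="two-group", rng=rng)
        R = pt.sample_correlation(df, "two-group")
        off = R[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.2)  # raw pooling would give ~1
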