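"""Learning-model regressors, design matrices, and the Gaussian GLM."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import approx_fprime
from scipy.stats import norm

from distractor_learn import (DegenerateDesignError,
                              DegenerateLikelihoodError, ParameterVector,
                              accumulator_predictions, build_design_matrix,
                              categorical_regressor, generate_sequence,
                              global_decay_regressor, log_likelihood,
                              n_free_params, predict_rt, priming_regressors,
                              rl_predictions)
from distractor_learn.design import ExperimentDesign
from distractor_learn.models import MODEL_SPECS, DesignBuilder

from conftest import (make_sequence, oracle_accumulator, oracle_categorical,
                      oracle_rl)


class TestGlobalDecay:
    def test_first_element_is_one_for_any_rate(self):
        for b in (1e-6, 0.015, 0.7, 5.0):
            assert global_decay_regressor(10, b)[0] == 1.0

    def test_zero_rate_limit_is_all_ones(self):
        assert np.all(global_decay_regressor(8, 0.0) == 1.0)

    def test_closed_form(self):
        v = global_decay_regressor(3, math.log(2.0))
        assert v[1] == pytest.approx(0.5, abs=1e-15)
        assert v[2] == pytest.approx(0.25, abs=1e-15)

    def test_strictly_decreasing_for_positive_rate(self):
        v = global_decay_regressor(50, 0.015)
        assert np.all(np.diff(v) < 0)


class TestStateModels:
    def test_accumulator_unvisited_location_predicts_zero(
            self, one_block_sequence):
        preds = accumulator_predictions(one_block_sequence, 1.0)
        assert preds[0] == 0.0

    def test_accumulator_closed_form_after_three_visits(self):
        # distractor at location 1 on four consecutive trials
        seq = make_sequence([(1, 1, 3)] * 4, hp_location=1)
        preds = accumulator_predictions(seq, 1.0)
        assert preds[3] == pytest.approx(1.0 - math.exp(-3.0), abs=1e-12)

    def test_accumulator_reset_zeroes_each_block(self, two_block_sequence):
        preds = accumulator_predictions(two_block_sequence, 1.0,
                                        reset_per_block=True)
        f = two_block_sequence.frame
        present = f[f["distractor_present"] == 1].reset_index()
        first_of_block = present.groupby("block").head(1).index
        assert np.all(preds[first_of_block] == 0.0)

    def test_rl_initializes_at_one_sixth_estimate(self, one_block_sequence):
        assert rl_predictions(one_block_sequence, 0.3)[0] == \
            pytest.approx(0.16667)

    def test_rl_zero_alpha_limit_is_constant(self, one_block_sequence):
        preds = rl_predictions(one_block_sequence, 1e-12)
        assert np.allclose(preds, 0.16667, atol=1e-9)

    def test_rl_single_delta_step_by_hand(self):
        # one delta-rule update: the visited location moves halfway to 1,
        # every other location moves halfway to 0
        seq = make_sequence([(1, 2, 0), (1, 2, 0)], hp_location=2)
        assert rl_predictions(seq, 0.5)[1] == pytest.approx(0.583335,
                                                            abs=1e-12)
        seq = make_sequence([(1, 2, 0), (1, 4, 0)], hp_location=2)
        assert rl_predictions(seq, 0.5)[1] == pytest.approx(0.083335,
                                                            abs=1e-12)

    def test_categorical_initial_full_tie_scores_one(self, one_block_sequence):
        assert categorical_regressor(one_block_sequence)[0] == 1.0

    def test_categorical_argmax_and_ties(self):
        # counts l2:2, l5:1 -> distractor at 2 scores 1, at 5 scores 0;
        # after 2-2 tie between l2 and l5, either scores 1
        seq = make_sequence([(1, 2, 0), (1, 2, 0), (1, 5, 0),
                             (1, 2, 0), (1, 5, 0),
                             (1, 5, 0), (1, 2, 0), (1, 5, 0)], hp_location=2)
        preds = categorical_regressor(seq)
        assert preds[3] == 1.0   # counts 2 at l2 vs 1 at l5
        assert preds[4] == 0.0   # l5 (1) below the max (3)
        assert preds[6] == 1.0   # 3-3 tie: either tied location scores 1
        assert preds[7] == 0.0   # l5 (3) below l2 (4) again
        # recompute expectations with the oracle to avoid hand-count slips
        assert preds.tolist() == oracle_categorical(seq, reset=False)

    @pytest.mark.parametrize("reset", [False, True])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_on_short_sequences(self, seed, reset):
        """Vectorized trajectories equal the straight-loop references."""
        design = ExperimentDesign(n_blocks=2, trials_per_block=60, seed=seed)
        seq = generate_sequence(design, f"s{seed}")
        for b in (0.2, 1.0):
            np.testing.assert_allclose(
                accumulator_predictions(seq, b, reset),
                oracle_accumulator(seq, b, reset), rtol=0, atol=1e-12)
        for a in (0.1, 0.55):
            np.testing.assert_allclose(
                rl_predictions(seq, a, reset),
                oracle_rl(seq, a, reset), rtol=0, atol=1e-12)
        np.testing.assert_allclose(
            categorical_regressor(seq, reset),
            oracle_categorical(seq, reset), rtol=0, atol=0)

    def test_accumulator_monotone_without_reset(self, two_block_sequence):
        """Counts only grow, so the prediction at any fixed location never
        decreases across its successive distractor visits."""
        f = two_block_sequence.frame
        preds = accumulator_predictions(two_block_sequence, 0.5)
        locs = f.loc[f["distractor_present"] == 1,
                     "distractor_location"].to_numpy()
        for l in range(6):
            p = preds[locs == l]
            assert np.all(np.diff(p) >= 0)

    def test_rl_decreases_only_when_distractor_elsewhere(
            self, one_block_sequence):
        seq = one_block_sequence
        locs = seq.frame.loc[seq.frame["distractor_present"] == 1,
                             "distractor_location"].to_numpy()
        preds = rl_predictions(seq, 0.4)
        for l in range(6):
            idx = np.flatnonzero(locs == l)
            for i, j in zip(idx[:-1], idx[1:]):
                if j == i + 1:  # consecutive visits: prediction grew
                    assert preds[j] >= preds[i]

    def test_large_rate_nests_visited_indicator(self, one_block_sequence):
        """As the location decay rate grows, the graded accumulator
        prediction converges to 1{location has hosted a distractor}."""
        preds = accumulator_predictions(one_block_sequence, 50.0)
        counts_visited = np.asarray(
            oracle_accumulator(one_block_sequence, 50.0, False)) > 0
        assert np.allclose(preds, counts_visited.astype(float), atol=1e-12)

    @pytest.mark.parametrize("pair", [(1, 4), (2, 5), (3, 6)])
    def test_reset_variants_match_on_a_single_block(self, pair,
                                                    one_block_sequence):
        base, reset = pair
        spec = MODEL_SPECS[base]
        if spec.regressor == "categorical":
            a = categorical_regressor(one_block_sequence, False)
            b = categorical_regressor(one_block_sequence, True)
        elif spec.state == "rl":
            a = rl_predictions(one_block_sequence, 0.3, False)
            b = rl_predictions(one_block_sequence, 0.3, True)
        else:
            a = accumulator_predictions(one_block_sequence, 0.7, False)
            b = accumulator_predictions(one_block_sequence, 0.7, True)
        np.testing.assert_array_equal(a, b)


class TestPriming:
    def test_three_trial_type_coding(self):
        seq = make_sequence([
            (1, None, 0),  # absent
            (1, 2, 0),     # present after absent -> (1, 0)
            (1, 2, 0),     # repetition -> (0, 1)
            (1, 4, 0),     # change -> (0, 0)
            (1, None, 0),
            (1, 4, 0),     # present after absent
        ], hp_location=2)
        prev_absent, repetition = priming_regressors(seq)
        # four present trials: after-absent, repetition, change, after-absent
        assert prev_absent.tolist() == [1.0, 0.0, 0.0, 1.0]
        assert repetition.tolist() == [0.0, 1.0, 0.0, 0.0]


class TestDesignMatrix:
    @pytest.mark.parametrize("model_id,expected", [
        (1, 6), (2, 6), (3, 5), (4, 6), (5, 6), (6, 5), (7, 5), (8, 4),
        (9, 4)])
    def test_free_parameter_counts(self, model_id, expected):
        assert n_free_params(model_id) == expected

    def test_rows_exclude_first_trial_of_each_block(self, exp1_sequence):
        pv = ParameterVector.from_natural(3, {
            "b_global": 0.015, "beta_intercept": 0.9, "beta_global_decay": 0.1,
            "beta_categorical": -0.04, "beta_prev_absent": 0.0})
        dm = build_design_matrix(pv, exp1_sequence)
        f = exp1_sequence.frame
        n_present = (f["distractor_present"] == 1).sum()
        first_present = ((f["distractor_present"] == 1)
                         & (f["trial_in_block"] == 1)).sum()
        assert dm.X.shape == (n_present - first_present, 4)

    def test_continuous_columns_are_standardized(self, exp1_sequence):
        pv = ParameterVector.from_natural(1, {
            "b_global": 0.02, "b_distractor": 0.3, "beta_intercept": 0.9,
            "beta_global_decay": 0.1, "beta_distractor_prediction": -0.05,
            "beta_prev_absent": 0.0})
        dm = build_design_matrix(pv, exp1_sequence)
        for name in ("global_decay", "distractor_prediction"):
            col = dm.X[:, dm.columns.index(name)]
            assert abs(col.mean()) < 1e-12
            assert col.std() == pytest.approx(1.0, abs=1e-12)
        # dummies untouched
        cat = dm.X[:, dm.columns.index("prev_absent")]
        assert set(np.unique(cat)) <= {0.0, 1.0}

    def test_rt_and_accuracy_filters_drop_rows(self, exp1_sequence):
        pv = ParameterVector.from_natural(3, {
            "b_global": 0.015, "beta_intercept": 0.9, "beta_global_decay": 0.1,
            "beta_categorical": -0.04, "beta_prev_absent": 0.0})
        n = exp1_sequence.n_trials
        rt = np.full(n, 800.0)
        acc = np.ones(n, int)
        base = build_design_matrix(pv, exp1_sequence, rt, acc)
        idx = base.included[:3]
        rt[idx[0]] = 150.0   # below the fast-guess cutoff
        acc[idx[1]] = 0      # inaccurate
        dm = build_design_matrix(pv, exp1_sequence, rt, acc)
        assert dm.X.shape[0] == base.X.shape[0] - 2
        assert idx[0] not in dm.included and idx[1] not in dm.included

    def test_too_few_rows_raises(self):
        seq = make_sequence([(1, 1, 0), (1, 2, 0), (1, 3, 0), (1, 4, 0)],
                            hp_location=1)
        pv = ParameterVector.from_natural(3, {
            "b_global": 0.015, "beta_intercept": 0.9, "beta_global_decay": 0.1,
            "beta_categorical": -0.04, "beta_prev_absent": 0.0})
        with pytest.raises(DegenerateDesignError):
            build_design_matrix(pv, seq)


class TestPredictAndLikelihood:
    def test_intercept_only_prediction(self):
        X = np.zeros((5, 4)); X[:, 0] = 1.0
        mu = predict_rt(X, [0.895, 0.0, 0.0, 0.0])
        assert np.allclose(mu, 0.895)

    def test_single_row_dot_product(self):
        assert predict_rt(np.array([[1.0, 1.0, 0.0, 0.0]]),
                          [0.9, -0.04, 0.0, 0.0])[0] == pytest.approx(0.86)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="columns"):
            predict_rt(np.ones((3, 4)), [1.0, 2.0])

    def test_closed_form_two_point_example(self):
        y = np.array([0.6, 0.4]); mu = np.array([0.5, 0.5])
        ll, sigma = log_likelihood(y, mu)
        assert sigma == pytest.approx(0.1)
        assert ll == pytest.approx(-2.0 * (0.5 + math.log(0.1 *
                                                          math.sqrt(2 * math.pi))))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_closed_form_matches_naive_density_sum(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 200))
        y = r.normal(0.8, 0.2, n)
        mu = r.normal(0.8, 0.05, n)
        ll, sigma = log_likelihood(y, mu)
        naive = norm.logpdf(y, loc=mu, scale=sigma).sum()
        assert abs(ll - naive) <= 1e-10

    def test_residual_scaling_property(self, rng):
        y = rng.normal(0.8, 0.1, 50)
        mu = np.full(50, 0.8)
        ll1, s1 = log_likelihood(y, mu)
        y2 = mu + 3.0 * (y - mu)
        ll2, s2 = log_likelihood(y2, mu)
        assert s2 == pytest.approx(3.0 * s1)
        assert ll2 == pytest.approx(ll1 - 50 * math.log(3.0))

    def test_permutation_invariance(self, rng):
        y = rng.normal(0.8, 0.1, 40)
        mu = rng.normal(0.8, 0.02, 40)
        perm = rng.permutation(40)
        assert log_likelihood(y, mu)[0] == \
            pytest.approx(log_likelihood(y[perm], mu[perm])[0], abs=1e-12)

    def test_zero_residuals_raise(self):
        with pytest.raises(DegenerateLikelihoodError):
            log_likelihood(np.ones(5), np.ones(5))


class TestObjectiveGradient:
    @pytest.mark.parametrize("model_id", list(range(1, 10)))
    def test_analytic_gradient_matches_numeric(self, model_id, exp1_sequence,
                                               rng):
        from distractor_learn.inference import _SubjectModelProblem
        from distractor_learn.data import SubjectData
        n = exp1_sequence.n_trials
        data = SubjectData(exp1_sequence,
                           rng.uniform(500, 1200, n), np.ones(n, int))
        p = _SubjectModelProblem(model_id, data)
        pm = np.zeros(p.d); pv = np.full(p.d, 6.25)
        x = rng.standard_normal(p.d) * 0.7
        x[:p.n_nonlinear] -= 2.0
        f, g = p.neg_log_post_grad(x, pm, pv)
        assert f == pytest.approx(-p.log_post(x, pm, pv), abs=1e-9)
        gn = approx_fprime(x, lambda z: p.neg_log_post_grad(z, pm, pv)[0],
                           1e-7)
        np.testing.assert_allclose(g, gn, rtol=1e-3, atol=1e-4)
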