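"""Tests of the Bernoulli GLM-HMM: design matrices, EM, model comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

import modeseek as mk
from modeseek import glmhmm
from modeseek.exceptions import ConfigurationError, OrderingError

from conftest import make_trials


def brute_force_loglik(log_b, A, pi):
    """Log-likelihood by exhaustive summation over all state paths."""
    T, K = log_b.shape
    total = -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(pi[path[0]]) + log_b[0, path[0]]
        for t in range(1, T):
            lp += np.log(A[path[t - 1], path[t]]) + log_b[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


def random_hmm_instance(rng, T):
    log_b = rng.normal(loc=-1.0, scale=1.0, size=(T, 2))
    a = rng.uniform(0.6, 0.95, size=2)
    A = np.array([[a[0], 1 - a[0]], [1 - a[1], a[1]]])
    pi = np.array([0.5, 0.5])
    return log_b, A, pi


class TestBuildDesign:
    def test_lagged_response_within_session(self):
        trials = make_trials([1, 0, 1])
        trials = glmhmm.rebuild_prev_response(trials)
        X, y, first = glmhmm.build_design(trials)
        np.testing.assert_array_equal(X[:, 1], [0, 1, 0])
        np.testing.assert_array_equal(y, [1, 0, 1])
        assert first[0] and not first[1:].any()

    def test_lag_resets_at_session_start(self):
        trials = make_trials([1, 1, 1, 1], sessions=[0, 0, 1, 1])
        trials = glmhmm.rebuild_prev_response(trials)
        X, _, first = glmhmm.build_design(trials)
        np.testing.assert_array_equal(X[:, 1], [0, 1, 0, 1])
        np.testing.assert_array_equal(first, [True, False, True, False])

    def test_noise_trials_have_zero_contrast_regressor(self, two_state_trials):
        X, _, _ = glmhmm.build_design(two_state_trials)
        noise = (two_state_trials["stim_class"] == "noise").to_numpy()
        assert (X[noise, 0] == 0.0).all()

    def test_levels_coding(self, two_state_trials):
        X, _, _ = glmhmm.build_design(two_state_trials, contrast_coding="levels")
        cls = two_state_trials["stim_class"].to_numpy()
        assert (X[cls == "noise", 0] == 0).all()
        assert (X[cls == "low", 0] == 1).all()
        assert (X[cls == "inducer", 0] == 2).all()

    def test_unsorted_input_rejected(self):
        trials = make_trials([1, 0, 1])
        with pytest.raises(OrderingError):
            glmhmm.build_design(trials.iloc[::-1].reset_index(drop=True))


class TestOneStateGLM:
    def test_matches_statsmodels_logit(self, two_state_trials):
        """Independent oracle: statsmodels MLE on the same design."""
        import statsmodels.api as sm

        X, y, _ = glmhmm.build_design(two_state_trials)
        ours = glmhmm.fit_one_state_glm(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.weights.as_array(), ref.params, atol=1e-5)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-5)

    def test_recovers_generating_weights_within_2se(self):
        rng = np.random.default_rng(30)
        n = 5000
        contrast = rng.choice([0.0, 0.7, 0.4], size=n)
        y = np.zeros(n, dtype=int)
        y_prev = 0
        for t in range(n):
            p = 1 / (1 + np.exp(-(4.0 * contrast[t] + 0.5 * y_prev)))
            y[t] = rng.random() < p
            y_prev = y[t]
        X = np.column_stack([contrast, np.r_[0, y[:-1]]])
        import statsmodels.api as sm

        fit = glmhmm.fit_one_state_glm(X, y)
        se = sm.Logit(y, X).fit(disp=0).bse
        assert abs(fit.weights.beta_S - 4.0) < 2 * se[0]
        assert abs(fit.weights.beta_H - 0.5) < 2 * se[1]

    def test_null_regressors_give_null_weights(self):
        rng = np.random.default_rng(31)
        X = np.column_stack([rng.random(2000), rng.integers(0, 2, 2000)])
        y = rng.integers(0, 2, 2000)
        fit = glmhmm.fit_one_state_glm(X, y)
        assert np.all(np.abs(fit.weights.as_array()) < 0.3)


class TestEmissionLoglik:
    def test_zero_weights_give_log_half(self):
        X = np.random.default_rng(32).normal(size=(10, 2))
        ll = glmhmm.emission_loglik(np.zeros(2), X, np.ones(10, dtype=int))
        np.testing.assert_allclose(ll, np.log(0.5))

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(33)
        X = rng.normal(size=(10, 2))
        y = rng.integers(0, 2, 10)
        w = np.array([1.3, -0.7])
        p = 1 / (1 + np.exp(-X @ w))
        direct = np.where(y == 1, np.log(p), np.log(1 - p))
        np.testing.assert_allclose(glmhmm.emission_loglik(w, X, y), direct, atol=1e-12)

    def test_saturated_drive_is_finite(self):
        X = np.array([[1000.0, 0.0]])
        ll = glmhmm.emission_loglik(np.array([1.0, 0.0]), X, np.array([1]))
        assert ll[0] == pytest.approx(0.0, abs=1e-12)
        ll0 = glmhmm.emission_loglik(np.array([1.0, 0.0]), X, np.array([0]))
        assert np.isfinite(ll0[0])


class TestForwardBackward:
    def test_single_state_degenerates_to_sum(self):
        log_b = np.log(np.random.default_rng(34).random((20, 1)))
        gamma, _, ll = glmhmm.forward_backward(log_b, np.array([[1.0]]), np.array([1.0]))
        assert (gamma == 1.0).all()
        assert ll == pytest.approx(log_b.sum())

    def test_identical_likelihoods_symmetric_transitions(self):
        log_b = np.tile(np.log(0.3), (15, 2))
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        gamma, _, _ = glmhmm.forward_backward(log_b, A, np.array([0.5, 0.5]))
        np.testing.assert_allclose(gamma, 0.5)

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(35)
        for _ in range(25):
            T = int(rng.integers(1, 11))
            log_b, A, pi = random_hmm_instance(rng, T)
            _, _, ll = glmhmm.forward_backward(log_b, A, pi)
            assert ll == pytest.approx(brute_force_loglik(log_b, A, pi), abs=1e-8)

    def test_gamma_matches_path_enumeration(self):
        rng = np.random.default_rng(36)
        log_b, A, pi = random_hmm_instance(rng, 6)
        gamma, _, _ = glmhmm.forward_backward(log_b, A, pi)
        # posterior of z_2 = 0 by brute force
        num = -np.inf
        den = -np.inf
        for path in itertools.product(range(2), repeat=6):
            lp = np.log(pi[path[0]]) + log_b[0, path[0]]
            for t in range(1, 6):
                lp += np.log(A[path[t - 1], path[t]]) + log_b[t, path[t]]
            den = np.logaddexp(den, lp)
            if path[2] == 0:
                num = np.logaddexp(num, lp)
        assert gamma[2, 0] == pytest.approx(np.exp(num - den), abs=1e-10)

    def test_non_stochastic_transition_rejected(self):
        with pytest.raises(ConfigurationError):
            glmhmm.forward_backward(
                np.zeros((5, 2)), np.array([[0.7, 0.2], [0.5, 0.5]]), np.array([0.5, 0.5])
            )


class TestMSteps:
    def test_full_weight_on_one_state_reduces_to_mle(self, two_state_trials):
        X, y, _ = glmhmm.build_design(two_state_trials)
        config = glmhmm.HMMConfig(sigma2=1e12)
        gamma = np.column_stack([np.ones(len(y)), np.zeros(len(y))])
        w = glmhmm.m_step_weights(X, y, gamma, config)
        mle = glmhmm.fit_one_state_glm(X, y).weights.as_array()
        np.testing.assert_allclose(w[0], mle, atol=1e-5)

    def test_symmetric_responsibilities_give_identical_states(self, two_state_trials):
        X, y, _ = glmhmm.build_design(two_state_trials)
        gamma = np.full((len(y), 2), 0.5)
        w = glmhmm.m_step_weights(X, y, gamma, glmhmm.HMMConfig())
        np.testing.assert_allclose(w[0], w[1], atol=1e-8)

    def test_weight_update_never_decreases_penalized_objective(self, two_state_trials):
        X, y, _ = glmhmm.build_design(two_state_trials)
        rng = np.random.default_rng(37)
        gamma = rng.random((len(y), 2))
        config = glmhmm.HMMConfig()
        w0 = np.array([[0.5, 0.5], [0.5, 0.5]])
        w = glmhmm.m_step_weights(X, y, gamma, config, w_init=w0)
        for k in range(2):
            def obj(wk):
                return float(
                    gamma[:, k] @ glmhmm.emission_loglik(wk, X, y)
                    - wk @ wk / (2 * config.sigma2)
                )
            assert obj(w[k]) >= obj(w0[k]) - 1e-9

    def test_transition_update_is_normalized_count(self):
        xi = np.array([[30.0, 2.0], [3.0, 45.0]])
        A = glmhmm.m_step_transitions(xi, glmhmm.HMMConfig(alpha=1.0))
        np.testing.assert_allclose(A, xi / xi.sum(axis=1, keepdims=True))
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_self_transition_concentration_gives_near_identity(self):
        xi = np.array([[500.0, 1.0], [1.0, 500.0]])
        A = glmhmm.m_step_transitions(xi, glmhmm.HMMConfig())
        assert A[0, 0] > 0.99 and A[1, 1] > 0.99


class TestFitGLMHMM:
    def test_log_posterior_is_monotone(self, two_state_trials):
        fit = mk.fit_glm_hmm(two_state_trials)
        assert np.all(np.diff(fit.log_posterior_trace) > -1e-6)

    def test_state_zero_is_external_after_relabeling(self, two_state_trials):
        fit = mk.fit_glm_hmm(two_state_trials)
        sep = fit.weights[:, 0] - fit.weights[:, 1]
        assert sep[0] > sep[1]

    def test_one_state_data_prefers_one_state_model(self, design):
        # bias=0 so the generating model lies inside the fitted (no-intercept)
        # model class; otherwise the extra states can absorb the bias
        seq = mk.generate_trial_sequence(design, seed=40, n_trials=2000)
        tab = mk.simulate_null_observer(seq, seed=41, beta_S=3.0, bias=0.0)
        fit = mk.fit_glm_hmm(tab)
        X, y, _ = glmhmm.build_design(tab)
        one = glmhmm.fit_one_state_glm(X, y)
        assert glmhmm.delta_bic(fit, one) > 0
        assert np.all(np.abs(fit.weights[0] - fit.weights[1]) < 1.0)

    def test_deterministic(self, two_state_trials):
        a = mk.fit_glm_hmm(two_state_trials)
        b = mk.fit_glm_hmm(two_state_trials)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.loglik == b.loglik


class TestBIC:
    def test_arithmetic_example(self):
        assert glmhmm.compute_bic(-50.0, 2, 100) == pytest.approx(109.2103, abs=1e-4)

    def test_identical_models_penalized_by_parameter_count(self, two_state_trials):
        X, y, _ = glmhmm.build_design(two_state_trials)
        one = glmhmm.fit_one_state_glm(X, y)
        two_bic = glmhmm.compute_bic(one.loglik, 6, one.n_obs)
        assert two_bic - one.bic == pytest.approx(4 * np.log(one.n_obs))


class TestModeLabels:
    def _fit_with_gamma(self, gamma_ext):
        gamma = np.column_stack([gamma_ext, 1 - np.asarray(gamma_ext)])
        return glmhmm.GLMHMMFit(
            weights=np.array([[3.0, 0.1], [0.5, 2.0]]),
            A=np.eye(2), gamma=gamma, xi_sum=np.eye(2),
            loglik=0.0, bic=0.0, converged=True, n_iter=1, n_obs=len(gamma),
        )

    def test_labels_and_runs_from_posteriors(self):
        fit = self._fit_with_gamma([0.9, 0.6, 0.4, 0.2])
        labels = glmhmm.label_modes(fit)
        assert list(labels.labels) == ["external", "external", "internal", "internal"]
        np.testing.assert_array_equal(labels.run_lengths_trials, [2, 2])
        assert labels.occupancy_internal == pytest.approx(0.5)

    def test_run_length_seconds_conversion(self):
        fit = self._fit_with_gamma([0.9] * 59 + [0.1])
        labels = glmhmm.label_modes(fit, trial_duration=2.0)
        assert labels.run_lengths_seconds[0] == pytest.approx(118.0)
        # a run of 59.1 trials at 2 s/trial corresponds to 118.2 s
        assert 59.1 * 2.0 == pytest.approx(118.2)

    def test_degenerate_modes_warn(self):
        fit = glmhmm.GLMHMMFit(
            weights=np.array([[3.0, 0.1], [2.0, 0.5]]),
            A=np.eye(2), gamma=np.full((4, 2), 0.5), xi_sum=np.eye(2),
            loglik=0.0, bic=0.0, converged=True, n_iter=1, n_obs=4,
        )
        with pytest.warns(UserWarning, match="degenerate"):
            glmhmm.label_modes(fit)


class TestPermutationControl:
    def test_fixed_seed_reproduces_permutations(self, two_state_trials):
        a = glmhmm.permutation_control(two_state_trials, n_perm=2, seed=50)
        b = glmhmm.permutation_control(two_state_trials, n_perm=2, seed=50)
        assert a["observed"] == b["observed"]
        np.testing.assert_array_equal(a["permuted"], b["permuted"])

    def test_observed_equals_direct_fit(self, two_state_trials):
        res = glmhmm.permutation_control(two_state_trials, n_perm=1, seed=51)
        fit = mk.fit_glm_hmm(glmhmm.rebuild_prev_response(two_state_trials))
        X, y, _ = glmhmm.build_design(two_state_trials)
        one = glmhmm.fit_one_state_glm(X, y)
        assert res["observed"] == pytest.approx(glmhmm.delta_bic(fit, one), abs=1e-6)

    def test_permutation_rebuilds_lagged_regressor(self, two_state_trials):
        rng = np.random.default_rng(52)
        shuffled = glmhmm._permute_within_participant(two_state_trials, rng)
        check = glmhmm.rebuild_prev_response(shuffled)
        np.testing.assert_array_equal(
            shuffled["prev_response"].to_numpy(), check["prev_response"].to_numpy()
        )
        # same multiset of trials, different order
        assert sorted(shuffled["response"]) == sorted(two_state_trials["response"])
        assert not shuffled["response"].equals(two_state_trials["response"])
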