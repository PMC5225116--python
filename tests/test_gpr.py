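"""GP regression core: kernel algebra, NLML + gradients, posterior math.

Oracles: closed-form scalar cases, brute-force dense evaluation of the
posterior equations, central finite differences for the gradient, and
scikit-learn's GP implementation as an independent cross-check.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroload.gpr import (GPHyperparams, gram_matrix, length_scales,
                           make_model, negative_log_marginal_likelihood,
                           predict, predict_with_feature_subset, se_ard_kernel,
                           train_gpr)


def random_hyper(rng, d):
    return GPHyperparams(
        log_length_scales=rng.normal(0.0, 0.5, size=d),
        log_signal_variance=float(rng.normal(0.0, 0.3)),
        log_noise_variance=float(rng.normal(-1.0, 0.3)),
    )


class TestKernel:
    def test_zero_distance_returns_signal_variance(self):
        h = GPHyperparams(np.log([2.0, 3.0]), np.log(1.7), 0.0)
        x = np.array([0.4, -1.2])
        assert se_ard_kernel(x, x, h) == pytest.approx(1.7)

    def test_unit_separation_scalar_value(self):
        h = GPHyperparams(np.log([1.0]), np.log(1.0), 0.0)
        assert se_ard_kernel([0.0], [1.0], h) == pytest.approx(
            np.exp(-0.5), abs=1e-9)

    def test_scale_invariance_of_quadratic_form(self):
        h1 = GPHyperparams(np.log([1.0]), 0.0, 0.0)
        h2 = GPHyperparams(np.log([2.0]), 0.0, 0.0)
        assert se_ard_kernel([0.0], [1.0], h1) == pytest.approx(
            se_ard_kernel([0.0], [2.0], h2), abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        h = GPHyperparams(np.log([1.0, 1.0]), 0.0, 0.0)
        with pytest.raises(ValueError):
            se_ard_kernel([0.0], [1.0], h)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=2),
           st.lists(st.floats(-5, 5), min_size=2, max_size=2))
    def test_symmetry_and_bound(self, xp, xq):
        h = GPHyperparams(np.log([1.5, 0.7]), np.log(2.0), 0.0)
        kpq = se_ard_kernel(xp, xq, h)
        assert kpq == pytest.approx(se_ard_kernel(xq, xp, h), rel=1e-12)
        assert 0.0 < kpq <= 2.0 + 1e-12


class TestGram:
    def test_matches_elementwise_kernel_loop(self):
        rng = np.random.default_rng(0)
        h = random_hyper(rng, 3)
        X1, X2 = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
        K = gram_matrix(X1, X2, h)
        brute = np.array([[se_ard_kernel(a, b, h) for b in X2] for a in X1])
        assert np.allclose(K, brute, rtol=1e-12)

    def test_self_gram_symmetric_psd_with_signal_variance_diagonal(self):
        rng = np.random.default_rng(1)
        h = random_hyper(rng, 4)
        X = rng.normal(size=(6, 4))
        K = gram_matrix(X, X, h)
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), h.signal_variance)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_identical_rows_give_constant_matrix(self):
        h = GPHyperparams(np.log([1.0, 1.0]), np.log(0.9), 0.0)
        X = np.tile([0.3, -0.7], (4, 1))
        assert np.allclose(gram_matrix(X, X, h), 0.9)


class TestNLML:
    def test_scalar_closed_form_zero_target(self):
        # n=1, y=0, sigma_f^2 + sigma_n^2 = 1: NLML = log(2 pi) / 2.
        h = GPHyperparams(np.log([1.0]), np.log(0.4), np.log(0.6))
        v = negative_log_marginal_likelihood(h, [[0.0]], [0.0],
                                             with_grad=False)
        assert v == pytest.approx(0.5 * np.log(2 * np.pi), abs=1e-10)

    def test_scalar_closed_form_general_target(self):
        h = GPHyperparams(np.log([1.0]), np.log(0.8), np.log(0.5))
        y0, s = 1.3, 1.3
        v = negative_log_marginal_likelihood(h, [[2.0]], [y0],
                                             with_grad=False)
        expected = 0.5 * y0**2 / s + 0.5 * np.log(s) + 0.5 * np.log(2 * np.pi)
        assert v == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        h = random_hyper(rng, 3)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        _, grad = negative_log_marginal_likelihood(h, X, y)
        theta = h.to_vector()
        eps = 1e-6
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = eps
            fp = negative_log_marginal_likelihood(
                GPHyperparams.from_vector(theta + e), X, y, with_grad=False)
            fm = negative_log_marginal_likelihood(
                GPHyperparams.from_vector(theta - e), X, y, with_grad=False)
            fd = (fp - fm) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_agrees_with_sklearn_gp(self):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        ls = np.array([0.5, 1.0, 2.0, 4.0])
        sf2, sn2 = 1.8, 0.25
        h = GPHyperparams(np.log(ls), np.log(sf2), np.log(sn2))
        kernel = ConstantKernel(sf2, "fixed") * RBF(ls, "fixed")
        gp = GaussianProcessRegressor(kernel=kernel, alpha=sn2,
                                      optimizer=None).fit(X, y)
        ours = negative_log_marginal_likelihood(h, X, y, with_grad=False)
        assert ours == pytest.approx(-gp.log_marginal_likelihood(), rel=1e-10)


class TestPredict:
    def test_single_training_point_posterior(self):
        # k=1 everywhere, sigma_n^2=1: mean = 1/(1+1) = 0.5, latent
        # variance = 1 - 1/2 = 0.5.
        h = GPHyperparams(np.log([1.0]), np.log(1.0), np.log(1.0))
        model = make_model([[0.0]], [1.0], h)
        pred = predict(model, [[0.0]])
        assert pred.mean[0] == pytest.approx(0.5, abs=1e-12)
        assert pred.var_latent[0] == pytest.approx(0.5, abs=1e-12)
        assert pred.var_observed[0] == pytest.approx(1.5, abs=1e-12)

    def test_far_test_point_recovers_prior(self):
        rng = np.random.default_rng(4)
        h = GPHyperparams(np.log([1.0, 1.0]), np.log(1.3), np.log(0.1))
        model = make_model(rng.normal(size=(10, 2)), rng.normal(size=10), h)
        pred = predict(model, [[100.0, 100.0]])
        assert pred.mean[0] == pytest.approx(0.0, abs=1e-8)
        assert pred.var_latent[0] == pytest.approx(1.3, abs=1e-8)

    def test_noise_free_limit_interpolates_training_targets(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        h = GPHyperparams(np.log([1.0, 1.0]), np.log(1.0), np.log(1e-10))
        model = make_model(X, y, h)
        pred = predict(model, X)
        assert np.allclose(pred.mean, y, atol=1e-4)

    @pytest.mark.parametrize("seed,n,d", [(0, 10, 2), (1, 30, 5), (2, 50, 3)])
    def test_factorization_path_equals_dense_brute_force(self, seed, n, d):
        rng = np.random.default_rng(seed)
        h = random_hyper(rng, d)
        X = rng.normal(size=(n, d))
        y = rng.normal(size=n)
        Xs = rng.normal(size=(7, d))
        model = make_model(X, y, h)
        pred = predict(model, Xs)
        Ky_inv = np.linalg.inv(gram_matrix(X, X, h)
                               + h.noise_variance * np.eye(n))
        Ks = gram_matrix(Xs, X, h)
        mean_bf = Ks @ Ky_inv @ y
        var_bf = np.diag(gram_matrix(Xs, Xs, h) - Ks @ Ky_inv @ Ks.T)
        assert np.allclose(pred.mean, mean_bf, rtol=1e-8, atol=1e-12)
        assert np.allclose(pred.var_latent, var_bf, rtol=1e-8, atol=1e-10)

    def test_latent_variance_bounded_by_signal_variance(self):
        rng = np.random.default_rng(6)
        h = random_hyper(rng, 3)
        model = make_model(rng.normal(size=(20, 3)), rng.normal(size=20), h)
        pred = predict(model, rng.normal(size=(50, 3)))
        assert np.all(pred.var_latent >= 0.0)
        assert np.all(pred.var_latent <= h.signal_variance + 1e-10)


class TestTraining:
    def test_training_never_increases_nlml(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=40)
        model = train_gpr(X, y)
        assert model.nlml_final <= model.nlml_initial

    def test_all_zero_targets_predict_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 2))
        model = train_gpr(X, np.zeros(20))
        pred = predict(model, rng.normal(size=(5, 2)))
        assert np.allclose(pred.mean, 0.0, atol=1e-8)

    def test_recovers_prior_hyperparameters(self):
        # Data drawn from the model's own prior; trained log length
        # scales should land within 0.5 of the truth for every
        # dimension, and the noise variance within 30%.
        rng = np.random.default_rng(42)
        n, d = 300, 5
        X = rng.normal(size=(n, d))
        true = GPHyperparams(np.log([1.0, 1.0, 2.0, 2.0, 1.5]),
                             np.log(1.0), np.log(0.1))
        K = gram_matrix(X, X, true) + true.noise_variance * np.eye(n)
        y = np.linalg.cholesky(K) @ rng.standard_normal(n)
        model = train_gpr(X, y)
        err = np.abs(model.hyper.log_length_scales - true.log_length_scales)
        assert np.all(err < 0.5)
        assert abs(model.hyper.log_noise_variance
                   - true.log_noise_variance) < np.log(1.3)

    def test_irrelevant_feature_gets_longer_length_scale(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 2))
            y = np.sin(1.5 * X[:, 0]) + 0.1 * rng.normal(size=80)
            model = train_gpr(X, y)
            ls = model.hyper.length_scales
            wins += ls[1] > ls[0]
        assert wins >= 18

    def test_non_finite_initial_objective_rejected(self):
        with pytest.raises(ValueError):
            train_gpr(np.array([[np.nan]]), np.array([1.0]))


@pytest.fixture(scope="module")
def planted_model():
    rng = np.random.default_rng(10)
    n = 150
    X = rng.normal(size=(n, 6))
    y = X[:, 0] - 0.8 * X[:, 1] ** 2 + 0.05 * rng.normal(size=n)
    Xs = rng.normal(size=(60, 6))
    ys = Xs[:, 0] - 0.8 * Xs[:, 1] ** 2 + 0.05 * rng.normal(size=60)
    return train_gpr(X, y), Xs, ys


class TestFeatureSubset:

    def test_full_subset_identical_to_plain_predict(self, planted_model):
        model, Xs, _ = planted_model
        full = predict(model, Xs)
        sub = predict_with_feature_subset(model, Xs, np.arange(6))
        assert np.allclose(sub.mean, full.mean, rtol=1e-10)
        assert np.allclose(sub.var_latent, full.var_latent, rtol=1e-8,
                           atol=1e-12)

    def test_relevant_subset_predicts_irrelevant_subset_does_not(
            self, planted_model):
        from neuroload.evaluation import smse

        model, Xs, ys = planted_model
        good = predict_with_feature_subset(model, Xs, [0, 1])
        bad = predict_with_feature_subset(model, Xs, [2, 3, 4, 5])
        full = predict(model, Xs)
        assert smse(ys, good.mean) < smse(ys, full.mean) + 0.1
        assert smse(ys, bad.mean) > 0.8

    def test_single_feature_agrees_with_fresh_1d_model(self, planted_model):
        model, Xs, _ = planted_model
        sub = predict_with_feature_subset(model, Xs, [0])
        fresh = make_model(model.X[:, [0]], model.y, model.hyper.subset([0]))
        ref = predict(fresh, Xs[:, [0]])
        assert np.allclose(sub.mean, ref.mean, rtol=1e-12)

    def test_empty_subset_rejected(self, planted_model):
        model, Xs, _ = planted_model
        with pytest.raises(ValueError):
            predict_with_feature_subset(model, Xs, [])


class TestLengthScaleRanking:
    def test_ties_break_by_feature_index(self):
        h = GPHyperparams(np.log([2.0, 2.0, 2.0]), 0.0, 0.0)
        model = make_model(np.zeros((2, 3)), np.zeros(2), h,
                           feature_names=["a", "b", "c"])
        ranking = length_scales(model)
        assert ranking["feature"].tolist() == ["a", "b", "c"]
        assert ranking["rank"].tolist() == [1, 2, 3]

    def test_shorter_scale_ranks_first(self):
        h = GPHyperparams(np.log([3.0, 0.5, 1.0]), 0.0, 0.0)
        model = make_model(np.zeros((2, 3)), np.zeros(2), h)
        ranking = length_scales(model)
        assert ranking["feature_index"].tolist() == [1, 2, 0]


class TestSerialization:
    def test_model_round_trips_with_identical_predictions(self, tmp_path):
        from neuroload.gpr import load_model, save_model

        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        model = train_gpr(X, y, feature_names=["x", "y", "z"])
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        Xs = rng.normal(size=(5, 3))
        assert np.allclose(predict(loaded, Xs).mean,
                           predict(model, Xs).mean, rtol=1e-14)
        assert loaded.feature_names == ["x", "y", "z"]
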