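import math

import numpy as np
import pytest

from fermbed.gp import (
    GPError,
    GPFitConfig,
    GPHyperparams,
    GPModel,
    fit_gp,
    log_marginal_likelihood,
    matern52,
    posterior,
    sample_posterior,
)

# (1 + √5 + 5/3)·exp(−√5), frozen from a 25-digit symbolic evaluation
MATERN52_AT_1 = 0.5239941088318203


def test_matern52_values():
    assert matern52(0.0) == 1.0
    assert matern52(50.0) < 1e-15
    assert matern52(1.0) == pytest.approx(MATERN52_AT_1, rel=1e-12)
    with pytest.raises(ValueError):
        matern52(-0.1)


def _smooth_fixture(n=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 2))
    y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
    return X, y


def test_fit_near_interpolation_at_noise_floor():
    X, y = _smooth_fixture()
    model = fit_gp(X, y, GPFitConfig(fixed_noise=1e-6, seed=1, restarts=4))
    post = posterior(model, X)
    resid = np.abs(post.mean - y)
    # contract: reproduce training targets within 3 noise stddevs (de-standardized)
    assert resid.max() <= 3 * math.sqrt(1e-6) * model.y_scale
    assert resid.max() / np.abs(y).max() < 1e-5


def test_constant_targets_handled():
    rng = np.random.default_rng(2)
    X = rng.random((8, 3))
    model = fit_gp(X, np.full(8, 3.7))
    post = posterior(model, rng.random((20, 3)))
    assert np.allclose(post.mean, 3.7, atol=1e-6)


def test_fit_errors():
    with pytest.raises(GPError, match="prior-only"):
        fit_gp(np.array([[0.5, 0.5]]), np.array([1.0]))
    with pytest.raises(GPError):
        fit_gp(np.random.default_rng(0).random((5, 2)), np.array([1, 2, np.nan, 4, 5.0]))


def test_lml_single_point_closed_form():
    """N = 1, standardized y = 0, unit signal, floored noise."""
    model = GPModel(
        np.array([[0.5]]),
        np.array([0.0]),
        GPHyperparams(0.0, 1.0, (1.0,), 1e-6),
        y_mean=0.0,
        y_scale=1.0,
    )
    expected = -0.5 * math.log(2 * math.pi * (1 + 1e-6))
    assert log_marginal_likelihood(model) == pytest.approx(expected, abs=1e-12)


def test_lml_duplicate_point_finite():
    X = np.array([[0.3, 0.3], [0.3, 0.3], [0.7, 0.2]])
    model = GPModel(
        X, np.array([1.0, 1.0, 2.0]),
        GPHyperparams(0.0, 1.0, (0.5, 0.5), 1e-6), 0.0, 1.0,
    )
    assert np.isfinite(log_marginal_likelihood(model))


def test_lml_matches_dense_oracle():
    X, y = _smooth_fixture(n=12, seed=3)
    model = fit_gp(X, y, GPFitConfig(seed=0, restarts=4))
    hp = model.hyperparams
    ls = np.asarray(hp.length_scales)
    diff = X[:, None, :] - X[None, :, :]
    r = np.sqrt(((diff / ls) ** 2).sum(-1))
    sr = math.sqrt(5) * r
    K = hp.signal_variance * (1 + sr + sr**2 / 3) * np.exp(-sr)
    K += (hp.noise_variance + model.jitter) * np.eye(len(y))
    resid = model.y_std
    direct = (
        -0.5 * resid @ np.linalg.solve(K, resid)
        - 0.5 * np.linalg.slogdet(K)[1]
        - 0.5 * len(y) * math.log(2 * math.pi)
    )
    assert log_marginal_likelihood(model) == pytest.approx(direct, abs=1e-8)


def test_posterior_prior_reversion_and_training_variance():
    X, y = _smooth_fixture()
    model = fit_gp(X, y, GPFitConfig(fixed_noise=1e-6, seed=1, restarts=4))
    hp = model.hyperparams
    far = np.full((1, 2), 1e4)  # enormous ARD distance
    post = posterior(model, far)
    assert post.mean[0] == pytest.approx(model.y_mean, abs=1e-9 * abs(model.y_mean))
    assert post.cov[0, 0] == pytest.approx(model.y_scale**2 * hp.signal_variance, rel=1e-9)
    at_train = posterior(model, X)
    assert np.all(at_train.variance <= 1e-6 * hp.signal_variance * model.y_scale**2 + 1e-12)


def test_posterior_two_point_hand_algebra():
    """2 training points, hand-set hyperparameters, scalar closed-form solve."""
    ls, sv, nv = 0.5, 2.0, 0.01
    x1, x2, xq = 0.2, 0.8, 0.5
    X = np.array([[x1], [x2]])
    y = np.array([1.0, -1.0])
    model = GPModel(X, y, GPHyperparams(0.0, sv, (ls,), nv), y_mean=0.0, y_scale=1.0)

    def k(a, b):
        r = abs(a - b) / ls
        sr = math.sqrt(5) * r
        return sv * (1 + sr + sr * sr / 3) * math.exp(-sr)

    K = np.array([[k(x1, x1) + nv, k(x1, x2)], [k(x2, x1), k(x2, x2) + nv]])
    ks = np.array([k(xq, x1), k(xq, x2)])
    mean_hand = ks @ np.linalg.solve(K, y)
    var_hand = k(xq, xq) - ks @ np.linalg.solve(K, ks)
    post = posterior(model, np.array([[xq]]))
    assert post.mean[0] == pytest.approx(mean_hand, abs=1e-8)
    assert post.cov[0, 0] == pytest.approx(var_hand, abs=1e-8)


def test_sample_posterior_statistics():
    X, y = _smooth_fixture()
    model = fit_gp(X, y, GPFitConfig(seed=1, restarts=4))
    xq = np.array([[0.4, 0.6]])
    d1 = sample_posterior(model, xq, 1, seed=11)
    d2 = sample_posterior(model, xq, 1, seed=11)
    np.testing.assert_array_equal(d1, d2)

    post = posterior(model, xq)
    draws = sample_posterior(model, xq, 50_000, seed=3)[:, 0]
    se = post.stddev[0] / math.sqrt(50_000)
    assert abs(draws.mean() - post.mean[0]) < 3 * se
    assert abs(draws.var() - post.variance[0]) / post.variance[0] < 0.05

    # near-zero-variance posterior at a training input under the noise floor:
    # the spread of the draws collapses to the noise-floor scale
    m0 = fit_gp(X, y, GPFitConfig(fixed_noise=1e-6, seed=1, restarts=4))
    p0 = posterior(m0, X[:1])
    assert p0.stddev[0] <= 1e-3 * m0.y_scale * math.sqrt(m0.hyperparams.signal_variance)
    d = sample_posterior(m0, X[:1], 100, seed=0)
    assert np.allclose(d, p0.mean[0], atol=5 * p0.stddev[0] + 1e-12)


def test_information_never_hurts():
    """Posterior variance bounded by prior; duplicating a point cannot raise it."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(4, 12)
        X = rng.random((n, 2))
        y = rng.standard_normal(n)
        ls = tuple(rng.uniform(0.2, 2.0, 2))
        hp = GPHyperparams(0.0, float(rng.uniform(0.5, 3)), ls, float(rng.uniform(1e-4, 0.1)))
        model = GPModel(X, y, hp, float(y.mean()), 1.0)
        Xq = rng.random((6, 2))
        post = posterior(model, Xq)
        assert np.all(post.variance <= hp.signal_variance + 1e-8)
        dup = GPModel(
            np.vstack([X, X[:1]]), np.r_[y, y[0]], hp, float(y.mean()), 1.0
        )
        post_dup = posterior(dup, Xq)
        assert np.all(post_dup.variance <= post.variance + 1e-8)


def test_serialization_roundtrip():
    X, y = _smooth_fixture()
    model = fit_gp(X, y, GPFitConfig(seed=1, restarts=4))
    clone = GPModel.from_dict(model.to_dict())
    Xq = np.random.default_rng(1).random((7, 2))
    p1, p2 = posterior(model, Xq), posterior(clone, Xq)
    np.testing.assert_allclose(p1.mean, p2.mean, rtol=1e-12)
    np.testing.assert_allclose(p1.cov, p2.cov, rtol=0, atol=1e-12)
    # de-standardization round trip
    np.testing.assert_allclose(
        model.y_mean + model.y_scale * model.y_std, y, rtol=1e-12
    )


def test_posterior_mean_matches_sklearn():
    """Independent GP implementation agrees on a fixed-hyperparameter fixture."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern

    rng = np.random.default_rng(4)
    X = rng.random((15, 3))
    y = np.cos(4 * X[:, 0]) + X[:, 1] - 0.5 * X[:, 2]
    ls = (0.4, 0.7, 1.2)
    sv, nv = 1.5, 1e-4
    model = GPModel(X, y, GPHyperparams(0.0, sv, ls, nv), y_mean=0.0, y_scale=1.0)
    sk = GaussianProcessRegressor(
        kernel=ConstantKernel(sv, "fixed") * Matern(np.array(ls), "fixed", nu=2.5),
        alpha=nv,
        optimizer=None,
    ).fit(X, y)
    Xq = rng.random((10, 3))
    np.testing.assert_allclose(posterior(model, Xq).mean, sk.predict(Xq), atol=1e-4)
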