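"""Gaussian-process surrogates with ARD Matérn-5/2 kernel.

One independent GP is fitted per objective: constant mean (fixed at the
standardized-target mean of zero), a Matérn-5/2 covariance with one length
scale per input dimension (automatic relevance determination) and one learned
homoscedastic Gaussian noise variance.  Inputs live on the unit cube, targets
are standardized internally; hyperparameters maximize the log marginal
likelihood by multi-restart bounded L-BFGS with analytic gradients.

With fresh-mass campaigns running on the order of 10–30 experiments, dense
Cholesky linear algebra is exact and instantaneous; nothing here is
approximate beyond floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.stats import qmc

__all__ = [
    "GPError",
    "GPHyperparams",
    "GPFitConfig",
    "GPPosterior",
    "GPModel",
    "matern52",
    "fit_gp",
    "log_marginal_likelihood",
    "posterior",
    "sample_posterior",
]

NOISE_FLOOR = 1e-6
_SQRT5 = math.sqrt(5.0)


class GPError(RuntimeError):
    """Numerical or usage error in the GP surrogate."""


def matern52(r_scaled):
    """Matérn-5/2 correlation (1 + √5 r + 5r²/3)·exp(−√5 r) at scaled distance r."""
    r = np.asarray(r_scaled, dtype=float)
    if np.any(r < 0):
        raise ValueError("matern52: distance must be nonnegative")
    sr = _SQRT5 * r
    out = (1.0 + sr + sr * sr / 3.0) * np.exp(-sr)
    return float(out) if np.isscalar(r_scaled) else out


@dataclass(frozen=True)
class GPHyperparams:
    mean_constant: float
    signal_variance: float
    length_scales: tuple[float, ...]
    noise_variance: float

    def __post_init__(self) -> None:
        if self.signal_variance <= 0:
            raise GPError("signal_variance must be positive")
        if any(l <= 0 for l in self.length_scales):
            raise GPError("length scales must be positive")
        if self.noise_variance < NOISE_FLOOR:
            raise GPError(f"noise_variance must be >= {NOISE_FLOOR}")


@dataclass(frozen=True)
class GPFitConfig:
    """Hyperparameter search configuration (log-parameterized box bounds)."""

    restarts: int = 8
    seed: int = 0
    length_scale_bounds: tuple[float, float] = (0.05, 10.0)
    signal_bounds: tuple[float, float] = (0.05, 20.0)
    noise_bounds: tuple[float, float] = (NOISE_FLOOR, 1.0)
    fixed_noise: float | None = None  # pin noise variance (standardized units)
    maxiter: int = 200


@dataclass(frozen=True)
class GPPosterior:
    """Joint Gaussian posterior at query points, in objective units."""

    mean: np.ndarray
    cov: np.ndarray

    @property
    def variance(self) -> np.ndarray:
        return np.clip(np.diag(self.cov), 0.0, None)

    @property
    def stddev(self) -> np.ndarray:
        return np.sqrt(self.variance)


_JITTERS = (0.0, 1e-8, 1e-6, 1e-4)


def _chol_jittered(K: np.ndarray) -> tuple[np.ndarray, float]:
    for jit in _JITTERS:
        try:
            L = cholesky(K + jit * np.eye(K.shape[0]), lower=True)
            return L, jit
        except np.linalg.LinAlgError:
            continue
    raise GPError("kernel matrix not positive definite after jitter escalation to 1e-4")


def _scaled_sq_dists(X: np.ndarray, Z: np.ndarray, ls: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - Z[None, :, :]
    return np.sum((diff / ls) ** 2, axis=-1)


def _kernel(X: np.ndarray, Z: np.ndarray, sv: float, ls: np.ndarray) -> np.ndarray:
    r = np.sqrt(np.maximum(_scaled_sq_dists(X, Z, ls), 0.0))
    return sv * matern52(r)


class GPModel:
    """A fitted GP: hyperparameters, training set and cached factorization."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        hyperparams: GPHyperparams,
        y_mean: float,
        y_scale: float,
    ) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise GPError("training set shapes inconsistent")
        self.X = X
        self.y_raw = y
        self.y_mean = float(y_mean)
        self.y_scale = float(y_scale)
        self.y_std = (y - self.y_mean) / self.y_scale
        self.hyperparams = hyperparams
        ls = np.asarray(hyperparams.length_scales, dtype=float)
        K = _kernel(X, X, hyperparams.signal_variance, ls)
        K[np.diag_indices_from(K)] += hyperparams.noise_variance
        self.L, self.jitter = _chol_jittered(K)
        resid = self.y_std - hyperparams.mean_constant
        self.alpha = cho_solve((self.L, True), resid)

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        hp = self.hyperparams
        return {
            "hyperparams": {
                "mean_constant": hp.mean_constant,
                "signal_variance": hp.signal_variance,
                "length_scales": list(hp.length_scales),
                "noise_variance": hp.noise_variance,
            },
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "X": self.X.tolist(),
            "y": self.y_raw.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPModel":
        hp = d["hyperparams"]
        return cls(
            np.asarray(d["X"], dtype=float),
            np.asarray(d["y"], dtype=float),
            GPHyperparams(
                hp["mean_constant"],
                hp["signal_variance"],
                tuple(hp["length_scales"]),
                hp["noise_variance"],
            ),
            d["y_mean"],
            d["y_scale"],
        )


def _lml_and_grad(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    fixed_noise: float | None,
) -> tuple[float, np.ndarray]:
    """Negative LML and gradient wrt log-hyperparameters."""
    n_dim = X.shape[1]
    ls = np.exp(theta[:n_dim])
    sv = math.exp(theta[n_dim])
    nv = fixed_noise if fixed_noise is not None else math.exp(theta[n_dim + 1])
    N = X.shape[0]

    diff = X[:, None, :] - X[None, :, :]
    D = (diff / ls) ** 2  # (N, N, d)
    r2 = np.sum(D, axis=-1)
    r = np.sqrt(np.maximum(r2, 0.0))
    sr = _SQRT5 * r
    e = np.exp(-sr)
    M = (1.0 + sr + sr * sr / 3.0) * e
    K = sv * M
    K[np.diag_indices_from(K)] += nv
    try:
        L = cholesky(K + 1e-10 * np.eye(N), lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros_like(theta)
    alpha = cho_solve((L, True), y)
    lml = -0.5 * float(y @ alpha) - float(np.sum(np.log(np.diag(L)))) - 0.5 * N * math.log(2 * math.pi)

    Kinv = cho_solve((L, True), np.eye(N))
    W = np.outer(alpha, alpha) - Kinv
    grad = np.zeros_like(theta)
    # d/dlog(l_d): sv * (5/3)(1 + sr) e^{-sr} * D_d
    base = sv * (5.0 / 3.0) * (1.0 + sr) * e
    for d in range(n_dim):
        grad[d] = 0.5 * np.sum(W * (base * D[:, :, d]))
    grad[n_dim] = 0.5 * np.sum(W * (sv * M))
    if fixed_noise is None:
        grad[n_dim + 1] = 0.5 * np.trace(W) * nv
    return -lml, -grad


def fit_gp(X, y, config: GPFitConfig | None = None) -> GPModel:
    """Fit one GP to (unit-cube inputs, raw objective values).

    Targets are standardized internally; constant targets are handled with a
    zero-variance guard (unit scale), so the posterior mean reverts to the
    constant everywhere.
    """
    config = config or GPFitConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise GPError("need at least 2 observations; use a prior-only posterior below that")
    if y.shape != (X.shape[0],):
        raise GPError(f"target shape {y.shape} does not match {X.shape[0]} inputs")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise GPError("inputs and targets must be finite")

    y_mean = float(np.mean(y))
    y_scale = float(np.std(y))
    if y_scale < 1e-12:
        y_scale = 1.0
    y_std = (y - y_mean) / y_scale

    n_dim = X.shape[1]
    lb = np.log(
        [config.length_scale_bounds[0]] * n_dim + [config.signal_bounds[0]] + [config.noise_bounds[0]]
    )
    ub = np.log(
        [config.length_scale_bounds[1]] * n_dim + [config.signal_bounds[1]] + [config.noise_bounds[1]]
    )
    n_free = n_dim + (1 if config.fixed_noise is not None else 2)
    lb, ub = lb[:n_free], ub[:n_free]

    starts = [np.clip(np.log(np.r_[np.full(n_dim, 0.5), 1.0, 0.05][:n_free]), lb, ub)]
    if config.restarts > 1:
        sob = qmc.Sobol(d=n_free, scramble=True, rng=np.random.default_rng(config.seed))
        n_extra = config.restarts - 1
        u = sob.random_base2(max(1, math.ceil(math.log2(n_extra))))[:n_extra]
        starts.extend(lb + u * (ub - lb))

    best = None
    for theta0 in starts:
        res = minimize(
            _lml_and_grad,
            theta0,
            args=(X, y_std, config.fixed_noise),
            method="L-BFGS-B",
            jac=True,
            bounds=list(zip(lb, ub)),
            options={"maxiter": config.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = np.clip(best.x, lb, ub)
    ls = tuple(float(v) for v in np.exp(theta[:n_dim]))
    sv = float(math.exp(theta[n_dim]))
    nv = float(config.fixed_noise) if config.fixed_noise is not None else float(math.exp(theta[n_dim + 1]))
    hp = GPHyperparams(0.0, sv, ls, max(nv, NOISE_FLOOR))
    return GPModel(X, y, hp, y_mean, y_scale)


def log_marginal_likelihood(model: GPModel) -> float:
    """LML of the standardized, mean-subtracted targets under the fitted kernel."""
    resid = model.y_std - model.hyperparams.mean_constant
    N = resid.shape[0]
    return (
        -0.5 * float(resid @ model.alpha)
        - float(np.sum(np.log(np.diag(model.L))))
        - 0.5 * N * math.log(2 * math.pi)
    )


def posterior(model: GPModel, Xq) -> GPPosterior:
    """Joint posterior mean/covariance at query points, in objective units."""
    Xq = np.asarray(Xq, dtype=float)
    if Xq.ndim == 1:
        Xq = Xq[None, :]
    if Xq.size == 0:
        return GPPosterior(np.empty(0), np.empty((0, 0)))
    hp = model.hyperparams
    ls = np.asarray(hp.length_scales)
    Ks = _kernel(model.X, Xq, hp.signal_variance, ls)  # (N, Q)
    Kss = _kernel(Xq, Xq, hp.signal_variance, ls)
    mean_std = hp.mean_constant + Ks.T @ model.alpha
    V = solve_triangular(model.L, Ks, lower=True)
    cov_std = Kss - V.T @ V
    cov_std = 0.5 * (cov_std + cov_std.T)
    diag = np.diag(cov_std).copy()
    if np.any(diag < -1e-8):
        raise GPError("posterior covariance diagonal below clamping tolerance")
    np.fill_diagonal(cov_std, np.clip(diag, 0.0, None))
    mean = model.y_mean + model.y_scale * mean_std
    cov = model.y_scale**2 * cov_std
    return GPPosterior(mean, cov)


def posterior_cross_cov(model: GPModel, P, Q) -> np.ndarray:
    """Posterior covariance block Cov(f(P), f(Q)), in objective units."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    hp = model.hyperparams
    ls = np.asarray(hp.length_scales)
    Kp = _kernel(model.X, P, hp.signal_variance, ls)
    Kq = _kernel(model.X, Q, hp.signal_variance, ls)
    Vp = solve_triangular(model.L, Kp, lower=True)
    Vq = solve_triangular(model.L, Kq, lower=True)
    cross = _kernel(P, Q, hp.signal_variance, ls) - Vp.T @ Vq
    return model.y_scale**2 * cross


def sample_posterior(model: GPModel, Xq, n_draws: int, seed: int) -> np.ndarray:
    """Joint multivariate-normal posterior draws, shape (n_draws, |Xq|)."""
    if n_draws < 1:
        raise GPError("n_draws must be >= 1")
    post = posterior(model, Xq)
    q = post.mean.shape[0]
    if q == 0:
        return np.empty((n_draws, 0))
    cov = post.cov + 1e-10 * np.eye(q)
    try:
        L = cholesky(cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise GPError("posterior covariance not PSD after clamping") from exc
    z = np.random.default_rng(seed).standard_normal((q, n_draws))
    return (post.mean[:, None] + L @ z).T
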