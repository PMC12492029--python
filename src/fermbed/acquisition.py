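"""Batch acquisition: noisy expected hypervolume improvement (qNEHVI).

The batch value of q candidate media is the Monte-Carlo average, over joint
posterior draws at the already-observed inputs plus the candidates, of the
hypervolume gained by the candidate draws over the observed draws.  Drawing
the observed ("noisy") front afresh in every sample is what makes the
acquisition robust to observation noise: the incumbent front is itself
uncertain and is integrated out rather than taken at face value.

One fixed base-sample set is drawn per proposal run and reused for every
acquisition evaluation (common random numbers), so the inner optimization
maximizes a deterministic function.  A closed-form bi-objective EHVI is
provided as the exact single-point oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.stats import norm, qmc

from .design_space import DesignSpace, denormalize
from .gp import GPError, GPModel, posterior, posterior_cross_cov
from .pareto import hypervolume_2d_batch, hypervolume_improvement, pareto_front

__all__ = [
    "AcquisitionConfig",
    "ProposalBatch",
    "ehvi_2d_exact",
    "qnehvi",
    "propose_batch",
    "QNEHVI",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    mc_samples: int = 512
    seed: int = 0
    restarts: int = 16
    maxfev: int = 150  # refinement budget per restart (Nelder-Mead)
    batch_mode: str = "sequential-greedy"  # or "top-q"
    reference_point: tuple[float, float] = (0.0, 0.0)
    dedup_tol: float = 1e-6  # min pairwise distance, normalized units
    audit_mc_samples: int = 4096  # draws for final reported values

    def __post_init__(self) -> None:
        if self.mc_samples < 16:
            raise ValueError("mc_samples must be >= 16")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.batch_mode not in ("sequential-greedy", "top-q"):
            raise ValueError(f"unknown batch mode {self.batch_mode!r}")


@dataclass(frozen=True)
class ProposalBatch:
    """q proposed settings (physical units) with their acquisition values."""

    x_physical: np.ndarray  # (q, n)
    acq_values: tuple[float, ...]
    seed: int
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        if self.x_physical.ndim != 2:
            raise ValueError("x_physical must be (q, n)")


def _gauss_excess(mu: float, sigma: float, c: float) -> float:
    """E[(Y − c)+] for Y ~ N(mu, sigma²)."""
    if sigma < 1e-12:
        return max(mu - c, 0.0)
    z = (mu - c) / sigma
    return (mu - c) * norm.cdf(z) + sigma * norm.pdf(z)


def ehvi_2d_exact(mean, stddev, front, reference_point) -> float:
    """Closed-form expected hypervolume improvement for one candidate (m = 2).

    Decomposes the region not dominated by the front into vertical strips
    between the sorted front abscissae; independence of the two Gaussian
    marginals factorizes each strip's contribution into a width expectation
    times a height expectation, each a standard Gaussian excess integral.
    Zero predictive spread degrades to the deterministic improvement.
    """
    mu = np.asarray(mean, dtype=float)
    sd = np.asarray(stddev, dtype=float)
    ref = np.asarray(reference_point, dtype=float)
    if mu.shape != (2,) or sd.shape != (2,) or ref.shape != (2,):
        raise ValueError("mean, stddev and reference_point must have 2 components")
    if np.any(sd < 0):
        raise ValueError("stddev must be nonnegative")
    front = np.asarray(front, dtype=float).reshape(-1, 2)
    if np.all(sd < 1e-12):
        return hypervolume_improvement(front, ref, mu[None, :])

    if front.size:
        front = pareto_front(front)
        front = front[front[:, 0] > ref[0]]
    k = front.shape[0]
    if k:
        order = np.argsort(front[:, 0], kind="stable")
        a = front[order, 0]  # ascending
        b = front[order, 1]  # descending (nondominated)
    else:
        a = np.empty(0)
        b = np.empty(0)
    edges = np.concatenate(([ref[0]], a))  # strip j spans [edges[j], edges[j+1])
    heights = np.concatenate((np.maximum(b, ref[1]), [ref[1]]))  # blocking height per strip
    total = 0.0
    for j in range(k + 1):
        e_lo = edges[j]
        w = _gauss_excess(mu[0], sd[0], e_lo)
        if j < k:
            w -= _gauss_excess(mu[0], sd[0], edges[j + 1])
        h = _gauss_excess(mu[1], sd[1], heights[j])
        total += max(w, 0.0) * h
    return float(max(total, 0.0))


_JITTERS = (0.0, 1e-12, 1e-10, 1e-8, 1e-6, 1e-4)


def _chol_psd(cov: np.ndarray) -> np.ndarray:
    n = cov.shape[0]
    for jit in _JITTERS:
        try:
            return cholesky(cov + jit * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise GPError("posterior covariance not positive definite for sampling")


def _factor_psd(cov: np.ndarray) -> np.ndarray:
    """Factor L with L Lᵀ = cov for a (possibly singular) PSD matrix.

    Plain Cholesky when it succeeds; otherwise an eigendecomposition with
    negative eigenvalues clipped to zero, so exact duplicates get exactly
    zero conditional spread instead of jitter noise.
    """
    try:
        return cholesky(cov, lower=True)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(0.5 * (cov + cov.T))
        return V * np.sqrt(np.clip(w, 0.0, None))


class QNEHVI:
    """qNEHVI evaluator with frozen base samples (common random numbers).

    Built once per proposal run from the fitted per-objective models and the
    observed inputs.  Draws of the latent objectives at the observed inputs
    (the "noisy" incumbent front) are generated once; candidate draws are
    sampled from the exact Gaussian conditional given those observed draws,
    so ``value(candidates)`` is a deterministic function of the candidate set,
    every per-draw improvement is nonnegative, and growing a pending batch
    can only increase the value draw by draw.
    """

    def __init__(
        self,
        models: tuple[GPModel, GPModel],
        observed_X: np.ndarray,
        reference_point,
        mc_samples: int,
        seed: int,
        max_batch: int = 8,
    ) -> None:
        if len(models) != 2:
            raise ValueError("exactly two objective models required")
        self.models = models
        self.X_obs = np.atleast_2d(np.asarray(observed_X, dtype=float))
        self.ref = np.asarray(reference_point, dtype=float)
        self.S = int(mc_samples)
        n_obs = self.X_obs.shape[0]
        rng = np.random.default_rng(seed)
        self._Z_cand = [rng.standard_normal((max_batch, self.S)) for _ in models]
        self._f_obs = []   # observed-front draws per objective, (n_obs, S)
        self._W = []       # Σ_oo⁻¹ (f_obs − μ_o) per objective, (n_obs, S)
        self._L_obs = []
        for model, _ in zip(models, self._Z_cand):
            post = posterior(model, self.X_obs)
            L = _chol_psd(post.cov)
            z = rng.standard_normal((n_obs, self.S))
            f = post.mean[:, None] + L @ z
            self._f_obs.append(f)
            self._W.append(solve_triangular(L.T, z, lower=False))
            self._L_obs.append(L)
        Y_obs = np.stack(self._f_obs, axis=-1)  # (n_obs, S, 2)
        self._Y_obs = Y_obs.transpose(1, 0, 2)  # (S, n_obs, 2)
        self._hv_obs = hypervolume_2d_batch(self._Y_obs, self.ref)

    def values_per_draw(self, candidates) -> np.ndarray:
        """Per-draw hypervolume improvements, shape (mc_samples,)."""
        cand = np.atleast_2d(np.asarray(candidates, dtype=float))
        k = cand.shape[0]
        if k == 0:
            raise ValueError("empty candidate set")
        if k > self._Z_cand[0].shape[0]:
            raise ValueError("candidate batch exceeds the base-sample allocation")
        f_cand = []
        for model, Z, W, L_obs in zip(self.models, self._Z_cand, self._W, self._L_obs):
            post_c = posterior(model, cand)
            cross = posterior_cross_cov(model, cand, self.X_obs)  # (k, n_obs)
            cond_mean = post_c.mean[:, None] + cross @ W  # (k, S)
            B = solve_triangular(L_obs, cross.T, lower=True)
            schur = post_c.cov - B.T @ B
            L_c = _factor_psd(schur)
            f_cand.append(cond_mean + L_c @ Z[:k])
        Y_c = np.stack(f_cand, axis=-1).transpose(1, 0, 2)  # (S, k, 2)
        Y = np.concatenate([self._Y_obs, Y_c], axis=1)
        hv_all = hypervolume_2d_batch(Y, self.ref)
        return np.maximum(hv_all - self._hv_obs, 0.0)

    def value(self, candidates) -> float:
        return float(np.mean(self.values_per_draw(candidates)))


def qnehvi(
    models: tuple[GPModel, GPModel],
    candidate_batch,
    observed_inputs,
    config: AcquisitionConfig,
) -> float:
    """Monte-Carlo qNEHVI of a candidate batch (unit-cube coordinates)."""
    cand = np.atleast_2d(np.asarray(candidate_batch, dtype=float))
    ev = QNEHVI(
        models,
        observed_inputs,
        config.reference_point,
        config.mc_samples,
        config.seed,
        max_batch=max(8, cand.shape[0]),
    )
    return ev.value(cand)


def _refine(fun, x0: np.ndarray, maxfev: int):
    n = x0.shape[0]
    return minimize(
        fun,
        np.clip(x0, 0.0, 1.0),
        method="Nelder-Mead",
        bounds=[(0.0, 1.0)] * n,
        options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-10},
    )


def _min_dist(x: np.ndarray, others: list[np.ndarray]) -> float:
    if not others:
        return np.inf
    return min(float(np.linalg.norm(x - o)) for o in others)


def propose_batch(
    models: tuple[GPModel, GPModel],
    space: DesignSpace,
    observed_X,
    q: int,
    config: AcquisitionConfig,
) -> ProposalBatch:
    """Propose the next q experiments by maximizing qNEHVI over the cube.

    Sequential-greedy (default): points are selected one at a time, each
    maximizing the batch acquisition of the pending set plus the new point.
    Top-q: the q best distinct local optima of the single-point acquisition.
    Deterministic for a fixed seed.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    n_dim = space.dimension
    ev = QNEHVI(
        models,
        observed_X,
        config.reference_point,
        config.mc_samples,
        config.seed,
        max_batch=q,
    )

    def starts_for(j: int) -> np.ndarray:
        import math as _math

        ss = np.random.SeedSequence((config.seed, j))
        sob = qmc.Sobol(d=n_dim, scramble=True, rng=np.random.default_rng(ss))
        m = max(0, _math.ceil(_math.log2(config.restarts)))
        return sob.random_base2(m)[: config.restarts]

    if config.batch_mode == "sequential-greedy":
        pending: list[np.ndarray] = []
        acq_values: list[float] = []
        for j in range(q):
            def neg(x):
                return -ev.value(np.vstack(pending + [np.clip(x, 0.0, 1.0)]))

            results = []
            for x0 in starts_for(j):
                res = _refine(neg, x0, config.maxfev)
                results.append((float(-res.fun), np.clip(res.x, 0.0, 1.0)))
            results.sort(key=lambda t: -t[0])
            chosen = None
            for val, x in results:
                if _min_dist(x, pending) >= config.dedup_tol:
                    chosen = (val, x)
                    break
            if chosen is None:
                raise GPError(
                    "all acquisition restarts collapsed onto pending points; "
                    f"best values: {[round(v, 6) for v, _ in results[:5]]}"
                )
            pending.append(chosen[1])
            acq_values.append(chosen[0])
        X_cube = np.vstack(pending)
    else:  # top-q
        def neg1(x):
            return -ev.value(np.clip(x, 0.0, 1.0)[None, :])

        results = []
        for x0 in starts_for(0):
            res = _refine(neg1, x0, config.maxfev)
            results.append((float(-res.fun), np.clip(res.x, 0.0, 1.0)))
        results.sort(key=lambda t: -t[0])
        picked: list[np.ndarray] = []
        vals: list[float] = []
        for val, x in results:
            if _min_dist(x, picked) >= config.dedup_tol:
                picked.append(x)
                vals.append(val)
            if len(picked) == q:
                break
        if len(picked) < q:
            # fall back on ranked space-filling candidates to complete the batch
            extra = qmc.Sobol(
                d=n_dim, scramble=True, rng=np.random.default_rng(config.seed + 1)
            ).random(max(64, 8 * q))
            scored = sorted(
                ((ev.value(x[None, :]), x) for x in extra), key=lambda t: -t[0]
            )
            for val, x in scored:
                if _min_dist(x, picked) >= config.dedup_tol:
                    picked.append(x)
                    vals.append(float(val))
                if len(picked) == q:
                    break
        X_cube = np.vstack(picked)
        acq_values = vals

    return ProposalBatch(
        x_physical=denormalize(X_cube, space),
        acq_values=tuple(acq_values),
        seed=config.seed,
        config=config,
    )
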