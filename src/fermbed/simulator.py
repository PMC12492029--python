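"""Synthetic BY-2 batch-fermentation oracle.

A multi-substrate Monod-type kinetic model maps the five design parameters
(sucrose, ammonium, phosphate, nitrate, inoculum fresh mass) to noisy
(final FM, FM-increase) observations with daily sampled trajectories, so the
full design loop can be exercised end to end without a bioreactor.

Model sketch (fresh mass X g/L; nutrients in mM):

  μ(t)  = μmax · N/(K_N+N) · K_IN/(K_IN+N) · P0/(K_P+P0) · A0/(K_A+A0) · S/(K_S+S)
  X_cap = X0 + min(Y_S·S0, Y_NH4·A0 + Y_NO3·N0)
  dX/dt = μ · X · max(0, 1 − (X/X_cap)^s)
  dS/dt = −(1/Y_S)·dX/dt
  dN/dt = −(1/Y_NO3)·dX/dt, but only once growth has consumed the
          ammonium-funded biomass increment Y_NH4·A0 (ammonium and phosphate
          are taken up rapidly into implicit internal pools, so the growth law
          sees their initial concentrations and nitrate is drawn down only
          after the internal ammonium pool is spent)
  dA/dt = −k_A·A,   dP/dt = −k_P·P      (first-order disappearance from medium)

Nitrate plays a dual role: it is required (Monod term) yet inhibitory at high
concentration (K_IN term), and it bounds the nitrogen-funded biomass together
with ammonium.  Sucrose and the nitrogen pool cap the final biomass without
affecting the early growth rate; ammonium is strictly required (A0 = 0 means
no growth) but nearly saturating above a few mM.  The cap exponent s keeps
growth unperturbed until close to the cap, which is what lets sucrose or
ammonium reductions lower the final yield while leaving the 4-day growth rate
essentially unchanged — the qualitative behaviour the loop is meant to learn.

Integration is fixed-step RK4 for bit-reproducibility; observation noise is
multiplicative lognormal (mean one, coefficient of variation ``noise_cv``)
applied independently to each sampled FM value.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .design_space import (
    PARAM_COLUMNS,
    SHEET_COLUMNS,
    DesignSpace,
    default_design_space,
    sobol_design,
)

__all__ = [
    "SimulatorParams",
    "Trajectory",
    "SimulatorError",
    "simulate_batch",
    "observe",
    "generate_historical",
    "simulate_sheet",
]


class SimulatorError(ValueError):
    pass


@dataclass(frozen=True)
class SimulatorParams:
    """Kinetic constants and run settings of the synthetic oracle.

    Defaults were calibrated once so that a mid-range medium (sucrose 100 mM,
    ammonium 20 mM, phosphate 5 mM, nitrate 40 mM, inoculum 15 g/L) crosses
    100 g/L between days 3 and 6 and finishes between 100 and 200 g/L, and so
    that the qualitative nutrient-response contracts in the test suite hold.
    """

    mu_max: float = 0.03        # 1/h, max specific growth rate of BY-2
    K_N: float = 5.0            # mM, nitrate half-saturation
    K_IN: float = 150.0         # mM, nitrate inhibition constant
    K_P: float = 2.0            # mM, phosphate half-saturation
    K_A: float = 0.25           # mM, ammonium requirement half-saturation
    K_S: float = 1.0            # mM, sucrose half-saturation
    Y_S: float = 2.0            # g FM per mM sucrose per L
    Y_NH4: float = 1.0          # g FM per mM ammonium per L
    Y_NO3: float = 3.2          # g FM per mM nitrate per L
    k_A: float = 0.05           # 1/h, ammonium uptake into internal pool
    k_P: float = 0.05           # 1/h, phosphate uptake into internal pool
    cap_sharpness: float = 12.0 # exponent s of the capacity factor
    noise_cv: float = 0.10      # CV of multiplicative lognormal FM noise
    horizon: float = 168.0      # h, batch duration (7 days)
    step: float = 0.5           # h, RK4 step
    sample_interval: float = 24.0  # h, daily FM sampling

    def __post_init__(self) -> None:
        positive = (
            "mu_max", "K_N", "K_IN", "K_P", "K_A", "K_S",
            "Y_S", "Y_NH4", "Y_NO3", "k_A", "k_P", "cap_sharpness",
            "horizon", "step", "sample_interval",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise SimulatorError(f"{name} must be positive")
        if self.noise_cv < 0:
            raise SimulatorError("noise_cv must be >= 0")
        n = self.sample_interval / self.step
        if abs(n - round(n)) > 1e-9:
            raise SimulatorError("step must divide sample_interval")
        m = self.horizon / self.sample_interval
        if abs(m - round(m)) > 1e-9:
            raise SimulatorError("sample_interval must divide horizon")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimulatorParams":
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class Trajectory:
    """One simulated batch: dense noise-free state plus daily sampled FM."""

    time: np.ndarray          # dense grid, h
    fm: np.ndarray            # g/L, noise-free
    sucrose: np.ndarray       # mM
    ammonium: np.ndarray      # mM
    nitrate: np.ndarray       # mM
    phosphate: np.ndarray     # mM
    sample_times: np.ndarray  # h, daily grid incl. 0 and horizon
    fm_sampled: np.ndarray    # g/L, noisy iff noise was on
    noise_free: bool


def simulate_batch(
    x,
    params: SimulatorParams | None = None,
    seed: int = 0,
    noise: bool = True,
) -> Trajectory:
    """Integrate one batch fermentation for design vector ``x``.

    ``x`` is (sucrose mM, ammonium mM, phosphate mM, nitrate mM, start FM g/L)
    in physical units.  Noise applies only to the daily sampled FM series.
    """
    p = params or SimulatorParams()
    x = np.asarray(x, dtype=float)
    if x.shape != (5,):
        raise SimulatorError("design vector must have 5 components")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise SimulatorError("design vector entries must be finite and nonnegative")
    S0, A0, P0, N0, X0 = x
    if X0 <= 0:
        raise SimulatorError("start fresh mass must be positive")

    x_cap = X0 + min(p.Y_S * S0, p.Y_NH4 * A0 + p.Y_NO3 * N0)
    ammonium_pool = p.Y_NH4 * A0  # biomass increment funded before nitrate draw-down

    def rhs(state: np.ndarray) -> np.ndarray:
        X, S, N, A, P = state
        S_ = max(S, 0.0)
        N_ = max(N, 0.0)
        mu = (
            p.mu_max
            * (N_ / (p.K_N + N_))
            * (p.K_IN / (p.K_IN + N_))
            * (P0 / (p.K_P + P0))
            * (A0 / (p.K_A + A0))
            * (S_ / (p.K_S + S_))
        )
        if x_cap <= X0:
            growth = 0.0
        else:
            growth = mu * X * max(0.0, 1.0 - (max(X, 0.0) / x_cap) ** p.cap_sharpness)
        dS = -growth / p.Y_S if S_ > 0 else 0.0
        dN = -growth / p.Y_NO3 if (X - X0 > ammonium_pool and N_ > 0) else 0.0
        return np.array([growth, dS, dN, -p.k_A * max(A, 0.0), -p.k_P * max(P, 0.0)])

    n_steps = int(round(p.horizon / p.step))
    time = np.linspace(0.0, p.horizon, n_steps + 1)
    states = np.empty((n_steps + 1, 5))
    states[0] = [X0, S0, N0, A0, P0]
    h = p.step
    for i in range(n_steps):
        s = states[i]
        k1 = rhs(s)
        k2 = rhs(s + 0.5 * h * k1)
        k3 = rhs(s + 0.5 * h * k2)
        k4 = rhs(s + h * k3)
        nxt = s + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        nxt[1:] = np.maximum(nxt[1:], 0.0)  # nutrients cannot go negative
        nxt[0] = max(nxt[0], s[0])          # FM nondecreasing (noise-free dynamics)
        states[i + 1] = nxt

    per_sample = int(round(p.sample_interval / p.step))
    sample_idx = np.arange(0, n_steps + 1, per_sample)
    sample_times = time[sample_idx]
    fm_sampled = states[sample_idx, 0].copy()
    if noise and p.noise_cv > 0:
        sigma = np.sqrt(np.log1p(p.noise_cv**2))
        z = np.random.default_rng(seed).standard_normal(fm_sampled.shape)
        fm_sampled = fm_sampled * np.exp(sigma * z - 0.5 * sigma**2)

    return Trajectory(
        time=time,
        fm=states[:, 0],
        sucrose=states[:, 1],
        ammonium=states[:, 3],
        nitrate=states[:, 2],
        phosphate=states[:, 4],
        sample_times=sample_times,
        fm_sampled=fm_sampled,
        noise_free=not (noise and p.noise_cv > 0),
    )


def observe(trajectory: Trajectory, window: float = 168.0) -> np.ndarray:
    """Objective vector (final FM, FM increase over ``window``) from samples.

    Final FM is the sampled value at the end of the batch; the increase is
    (FM(window) − FM(0)) / window in g/(L×h), both read off the (possibly
    noisy) daily series.
    """
    st = trajectory.sample_times
    idx = np.where(np.isclose(st, window, atol=1e-9))[0]
    if idx.size == 0:
        raise SimulatorError(
            f"window {window} h is not on the sample grid {st.tolist()}"
        )
    fm_w = trajectory.fm_sampled[idx[0]]
    final_fm = trajectory.fm_sampled[-1]
    increase = (fm_w - trajectory.fm_sampled[0]) / window
    return np.array([final_fm, increase])


def generate_historical(
    params: SimulatorParams | None = None,
    n: int = 10,
    seed: int = 0,
    space: DesignSpace | None = None,
    window: float | None = None,
) -> pd.DataFrame:
    """Synthetic stand-in for a historical starting batch of ``n`` experiments.

    Sobol-sampled designs are simulated with noise on and written in the
    standard sheet schema (iteration 0, status ``historical``).
    """
    p = params or SimulatorParams()
    if n < 2:
        raise SimulatorError("need at least 2 historical experiments")
    space = space or default_design_space()
    X = sobol_design(space, n, seed)
    rows = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    w = window if window is not None else p.horizon
    for i in range(n):
        traj = simulate_batch(X[i], p, seed=int(child_seeds[i]), noise=True)
        y = observe(traj, window=w)
        rows.append(
            {
                "experiment_id": f"B0_{i + 1:02d}",
                "iteration": 0,
                **{c: X[i, j] for j, c in enumerate(PARAM_COLUMNS)},
                "final_fm_g_L": y[0],
                "fm_increase_g_L_h": y[1],
                "status": "historical",
            }
        )
    return pd.DataFrame(rows, columns=list(SHEET_COLUMNS))


def simulate_sheet(
    sheet: pd.DataFrame,
    params: SimulatorParams | None = None,
    seed: int = 0,
    noise: bool = True,
    window: float | None = None,
) -> pd.DataFrame:
    """Fill the objective columns of all ``proposed`` rows of a sheet.

    Acts as the wet lab: each proposed row is simulated (per-row seed derived
    from ``seed`` and the experiment id) and flipped to ``completed``.
    """
    p = params or SimulatorParams()
    out = sheet.copy()
    w = window if window is not None else p.horizon
    for idx, row in out.iterrows():
        if row["status"] != "proposed":
            continue
        x = np.array([row[c] for c in PARAM_COLUMNS], dtype=float)
        row_seed = int(
            np.random.SeedSequence(
                [seed, *np.frombuffer(str(row["experiment_id"]).encode(), dtype=np.uint8)]
            ).generate_state(1)[0]
            % (2**31)
        )
        traj = simulate_batch(x, p, seed=row_seed, noise=noise)
        y = observe(traj, window=w)
        out.loc[idx, "final_fm_g_L"] = y[0]
        out.loc[idx, "fm_increase_g_L_h"] = y[1]
        out.loc[idx, "status"] = "completed"
    return out
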