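"""Closed-loop benchmark: adaptive design versus equal-budget Sobol sampling.

For one seed, both arms start from the same 10-run synthetic historical batch
and spend the same experimental budget (4 iterations × q = 4 runs) against the
noisy fermentation oracle; the score is the hypervolume of the observed
objective vectors over the reference point.  The adaptive arm should both win
on hypervolume and visibly narrow its proposed nitrate/phosphate levels as the
surrogate localizes the growth optimum.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import pareto
from .campaign import Campaign, CampaignConfig
from .design_space import PARAM_COLUMNS, default_design_space, sobol_design
from .simulator import SimulatorParams, generate_historical, observe, simulate_batch

__all__ = ["run_paired_benchmark", "bed_vs_sobol_once"]


def _iqr(v: np.ndarray) -> float:
    q1, q3 = np.percentile(v, [25, 75])
    return float(q3 - q1)


def bed_vs_sobol_once(
    seed: int,
    n_hist: int = 10,
    iterations: int = 4,
    q: int = 4,
    sim_params: SimulatorParams | None = None,
    restarts: int = 10,
    mc_samples: int = 384,
    maxfev: int = 120,
    workdir: str | Path | None = None,
) -> dict:
    """One paired comparison; returns hypervolumes and proposal spreads."""
    p = sim_params or SimulatorParams()
    space = default_design_space()
    hist = generate_historical(p, n=n_hist, seed=seed)
    ref = (0.0, 0.0)

    with tempfile.TemporaryDirectory(dir=workdir) as td:
        hist_path = Path(td) / "hist.csv"
        hist.to_csv(hist_path, index=False)
        cfg = CampaignConfig(
            q=q,
            optimization_iterations=iterations,
            seed=seed,
            restarts=restarts,
            mc_samples=mc_samples,
            maxfev=maxfev,
        )
        camp = Campaign.init(hist_path, cfg, Path(td) / "bed")
        camp.run(sim_params=p, noise=True)
        done = camp.obs[camp.obs["status"].isin(("historical", "completed"))]
        Y_bed = done[["final_fm_g_L", "fm_increase_g_L_h"]].to_numpy(dtype=float)
        bed_hv = pareto.hypervolume_2d(pareto.pareto_front(Y_bed), ref)
        it = done["iteration"].to_numpy(dtype=int)
        spread = {
            col: {
                "iter1": _iqr(done.loc[it == 1, col].to_numpy(dtype=float)),
                "iter4": _iqr(done.loc[it == iterations, col].to_numpy(dtype=float)),
            }
            for col in ("nitrate_mM", "phosphate_mM")
        }

    # equal-budget quasi-random arm: same historical data + 16 Sobol designs
    n_extra = iterations * q
    X = sobol_design(space, n_extra, seed=seed + 10_000)
    noise_seeds = np.random.SeedSequence((seed, 424242)).generate_state(n_extra) % (2**31)
    Y_extra = np.array(
        [
            observe(simulate_batch(X[i], p, seed=int(noise_seeds[i]), noise=True), p.horizon)
            for i in range(n_extra)
        ]
    )
    Y_hist = hist[["final_fm_g_L", "fm_increase_g_L_h"]].to_numpy(dtype=float)
    Y_sobol = np.vstack([Y_hist, Y_extra])
    sobol_hv = pareto.hypervolume_2d(pareto.pareto_front(Y_sobol), ref)

    return {
        "seed": seed,
        "bed_hv": float(bed_hv),
        "sobol_hv": float(sobol_hv),
        "bed_wins": bool(bed_hv > sobol_hv),
        "spread": spread,
        "n_runs": int(n_hist + n_extra),
        "bed_best_final_fm": float(Y_bed[:, 0].max()),
        "bed_best_fm_increase": float(Y_bed[:, 1].max()),
    }


def run_paired_benchmark(seeds, **kwargs) -> dict:
    """Paired benchmark over several seeds with summary statistics."""
    results = [bed_vs_sobol_once(int(s), **kwargs) for s in seeds]
    wins = sum(r["bed_wins"] for r in results)
    narrowing = {}
    for col in ("nitrate_mM", "phosphate_mM"):
        r1 = np.median([r["spread"][col]["iter1"] for r in results])
        r4 = np.median([r["spread"][col]["iter4"] for r in results])
        narrowing[col] = {"median_iqr_iter1": float(r1), "median_iqr_iter4": float(r4)}
    return {
        "per_seed": results,
        "wins": int(wins),
        "n_seeds": len(results),
        "win_fraction": wins / len(results),
        "median_bed_hv": float(np.median([r["bed_hv"] for r in results])),
        "median_sobol_hv": float(np.median([r["sobol_hv"] for r in results])),
        "iqr_narrowing": narrowing,
    }
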