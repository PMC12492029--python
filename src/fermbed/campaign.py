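"""Campaign management for the sequential design loop.

A campaign lives in a directory: configuration snapshot (YAML), the running
experiment sheet (CSV), serialized surrogate models (JSON) and reports
(JSON + figures).  The loop is: initialize from historical data, propose a
batch of q media, hand the proposals to the lab (or the bundled simulator),
ingest the measured objectives, refit, and repeat until the iteration budget
(default four optimization iterations) or an optional hypervolume-stall rule
fires.

All randomness flows from one campaign seed through a documented derivation
(numpy ``SeedSequence(campaign_seed, iteration, stream)``), so any partial
re-run from the same sheets reproduces proposals bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acquisition as acq
from . import gp, pareto, simulator
from .design_space import (
    OBJECTIVE_COLUMNS,
    PARAM_COLUMNS,
    SHEET_COLUMNS,
    DesignSpace,
    default_design_space,
    default_objectives,
    validate_observation,
)

__all__ = [
    "CampaignError",
    "CampaignConfig",
    "Campaign",
    "init_campaign",
    "read_sheet",
    "write_sheet",
]

log = logging.getLogger("fermbed")

STATUSES = {"historical", "proposed", "completed", "failed"}
_DONE = ("historical", "completed")


class CampaignError(RuntimeError):
    pass


@dataclass(frozen=True)
class CampaignConfig:
    q: int = 4
    optimization_iterations: int = 4
    seed: int = 0
    mc_samples: int = 512
    restarts: int = 16
    maxfev: int = 150
    batch_mode: str = "sequential-greedy"
    reference_point: tuple[float, float] = (0.0, 0.0)
    gp_restarts: int = 8
    stall_rule: bool = False
    stall_tol: float = 0.01  # relative HV gain below which an iteration "stalls"

    def __post_init__(self) -> None:
        if self.q < 1:
            raise CampaignError("q must be >= 1")
        if self.optimization_iterations < 1:
            raise CampaignError("optimization_iterations must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reference_point"] = list(self.reference_point)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CampaignConfig":
        d = dict(d)
        if "reference_point" in d:
            d["reference_point"] = tuple(d["reference_point"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CampaignConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _derived_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(keys).generate_state(1)[0] % (2**31))


def read_sheet(path) -> pd.DataFrame:
    """Read an experiment sheet, enforcing the exact column schema."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise CampaignError(f"sheet {path} is missing required columns: {missing}")
    bad = set(df["status"].dropna()) - STATUSES
    if bad:
        raise CampaignError(f"unknown status values: {sorted(bad)}")
    if df["experiment_id"].duplicated().any():
        dups = df.loc[df["experiment_id"].duplicated(), "experiment_id"].tolist()
        raise CampaignError(f"duplicate experiment ids: {dups}")
    return df[list(SHEET_COLUMNS)]


def write_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


class Campaign:
    """State and operations of one sequential-design campaign."""

    def __init__(
        self,
        directory: Path,
        config: CampaignConfig,
        observations: pd.DataFrame,
        iteration: int,
        hv_trail: list[float],
        space: DesignSpace | None = None,
    ) -> None:
        self.dir = Path(directory)
        self.config = config
        self.obs = observations
        self.iteration = iteration
        self.hv_trail = hv_trail
        self.space = space or default_design_space()
        self.objectives = default_objectives()
        self.models: tuple[gp.GPModel, gp.GPModel] | None = None

    # ------------------------------------------------------------------ io
    @classmethod
    def init(cls, historical_sheet, config: CampaignConfig, directory) -> "Campaign":
        """Start a campaign from a historical sheet (iteration 0)."""
        df = read_sheet(historical_sheet)
        done = df[df["status"].isin(_DONE)]
        if len(done) < 2:
            raise CampaignError(
                f"need at least 2 completed historical records, got {len(done)}"
            )
        df = df.copy()
        df.loc[df["status"].isin(_DONE), "iteration"] = 0
        df.loc[df["status"] == "completed", "status"] = "historical"
        camp = cls(Path(directory), config, df, iteration=0, hv_trail=[])
        camp._warn_out_of_range(df)
        camp._refit()
        camp.hv_trail = [camp._current_hv()]
        camp.save()
        return camp

    @classmethod
    def load(cls, directory) -> "Campaign":
        d = Path(directory)
        config = CampaignConfig.from_yaml(d / "config.yaml")
        obs = read_sheet(d / "observations.csv")
        with open(d / "state.json", encoding="utf-8") as fh:
            state = json.load(fh)
        camp = cls(d, config, obs, state["iteration"], state["hv_trail"])
        models_path = d / "models.json"
        if models_path.exists():
            with open(models_path, encoding="utf-8") as fh:
                md = json.load(fh)
            camp.models = tuple(gp.GPModel.from_dict(m) for m in md)
        return camp

    def save(self) -> None:
        self.dir.mkdir(parents=True, exist_ok=True)
        with open(self.dir / "config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=False)
        write_sheet(self.obs, self.dir / "observations.csv")
        with open(self.dir / "state.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"iteration": self.iteration, "hv_trail": self.hv_trail},
                fh,
                indent=2,
                sort_keys=True,
            )
        if self.models is not None:
            with open(self.dir / "models.json", "w", encoding="utf-8") as fh:
                json.dump([m.to_dict() for m in self.models], fh)

    # ------------------------------------------------------------ internals
    def _completed(self) -> pd.DataFrame:
        return self.obs[self.obs["status"].isin(_DONE)]

    def _warn_out_of_range(self, df: pd.DataFrame) -> None:
        for _, row in df[df["status"].isin(_DONE)].iterrows():
            x = row[list(PARAM_COLUMNS)].to_numpy(dtype=float)
            y = row[list(OBJECTIVE_COLUMNS)].to_numpy(dtype=float)
            report = validate_observation(x, y, self.space, self.objectives)
            for v in report:
                log.warning(
                    "experiment %s: %s=%s outside %s bound %s (kept)",
                    row["experiment_id"], v["name"], v["value"], v["kind"], v["bound"],
                )

    def _to_cube(self, X_phys: np.ndarray) -> np.ndarray:
        # tolerant affine map: legacy data may sit outside the box on purpose
        lo, hi = self.space.lower, self.space.upper
        return (X_phys - lo) / (hi - lo)

    def _refit(self) -> None:
        done = self._completed()
        X = self._to_cube(done[list(PARAM_COLUMNS)].to_numpy(dtype=float))
        models = []
        for j, col in enumerate(OBJECTIVE_COLUMNS):
            cfg = gp.GPFitConfig(
                restarts=self.config.gp_restarts,
                seed=_derived_seed(self.config.seed, self.iteration, j),
            )
            models.append(gp.fit_gp(X, done[col].to_numpy(dtype=float), cfg))
        self.models = tuple(models)

    def _current_hv(self) -> float:
        done = self._completed()
        Y = done[list(OBJECTIVE_COLUMNS)].to_numpy(dtype=float)
        return pareto.hypervolume_2d(
            pareto.pareto_front(Y), self.config.reference_point
        )

    # ------------------------------------------------------------------ ops
    def propose(self, force: bool = False) -> acq.ProposalBatch:
        """Propose the next q experiments (appended with status ``proposed``)."""
        if self.models is None:
            raise CampaignError("models not fitted; initialize the campaign first")
        pending = self.obs[self.obs["status"] == "proposed"]
        if len(pending) and not force:
            raise CampaignError(
                f"{len(pending)} pending proposals exist; ingest their results first "
                "(or pass force=True)"
            )
        t_next = self.iteration + 1
        cfg = acq.AcquisitionConfig(
            mc_samples=self.config.mc_samples,
            seed=_derived_seed(self.config.seed, t_next),
            restarts=self.config.restarts,
            maxfev=self.config.maxfev,
            batch_mode=self.config.batch_mode,
            reference_point=self.config.reference_point,
        )
        done = self._completed()
        X_obs = self._to_cube(done[list(PARAM_COLUMNS)].to_numpy(dtype=float))
        batch = acq.propose_batch(self.models, self.space, X_obs, self.config.q, cfg)
        rows = []
        for j in range(self.config.q):
            rows.append(
                {
                    "experiment_id": f"I{t_next}_{j + 1:02d}",
                    "iteration": t_next,
                    **{c: batch.x_physical[j, k] for k, c in enumerate(PARAM_COLUMNS)},
                    "final_fm_g_L": np.nan,
                    "fm_increase_g_L_h": np.nan,
                    "status": "proposed",
                }
            )
        self.obs = pd.concat([self.obs, pd.DataFrame(rows)], ignore_index=True)[
            list(SHEET_COLUMNS)
        ]
        sidecar = {
            "iteration": t_next,
            "seed": cfg.seed,
            "mc_samples": cfg.mc_samples,
            "batch_mode": cfg.batch_mode,
            "acquisition_values": list(batch.acq_values),
            "proposals": {
                f"I{t_next}_{j + 1:02d}": batch.x_physical[j].tolist()
                for j in range(self.config.q)
            },
        }
        with open(self.dir / f"proposals_iter{t_next}.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
        self.save()
        return batch

    def ingest(self, results: pd.DataFrame | str | Path) -> None:
        """Record measured objectives for previously proposed experiments."""
        if not isinstance(results, pd.DataFrame):
            results = pd.read_csv(results)
        needed = {"experiment_id", *OBJECTIVE_COLUMNS}
        missing = needed - set(results.columns)
        if missing:
            raise CampaignError(f"results sheet missing columns: {sorted(missing)}")
        known = set(self.obs["experiment_id"])
        for _, row in results.iterrows():
            eid = row["experiment_id"]
            if eid not in known:
                raise CampaignError(f"result references unknown experiment_id {eid!r}")
            mask = self.obs["experiment_id"] == eid
            if self.obs.loc[mask, "status"].iloc[0] not in ("proposed", "failed"):
                log.warning("experiment %s already resolved; result row skipped", eid)
                continue
            status = row.get("status", "completed")
            status = "completed" if pd.isna(status) else status
            if status not in ("completed", "failed"):
                raise CampaignError(f"result status for {eid!r} must be completed/failed")
            self.obs.loc[mask, "final_fm_g_L"] = row["final_fm_g_L"]
            self.obs.loc[mask, "fm_increase_g_L_h"] = row["fm_increase_g_L_h"]
            self.obs.loc[mask, "status"] = status
            if status == "completed":
                x = self.obs.loc[mask, list(PARAM_COLUMNS)].iloc[0].to_numpy(dtype=float)
                y = np.array([row["final_fm_g_L"], row["fm_increase_g_L_h"]], dtype=float)
                for v in validate_observation(x, y, self.space, self.objectives):
                    log.warning(
                        "experiment %s: %s=%s outside range (kept)",
                        eid, v["name"], v["value"],
                    )
        still_pending = self.obs[self.obs["status"] == "proposed"]
        if len(still_pending):
            log.warning(
                "%d proposals of iteration %d still pending; iteration counter unchanged",
                len(still_pending), self.iteration + 1,
            )
        else:
            self.iteration = int(self.obs.loc[self.obs["status"].isin(_DONE), "iteration"].max())
            self._refit()
            self.hv_trail.append(self._current_hv())
        self.save()

    def check_termination(self) -> tuple[bool, str]:
        """Budget- or stall-based stopping decision with a reason string."""
        if self.iteration >= self.config.optimization_iterations:
            return True, (
                f"iteration budget: completed {self.iteration} of "
                f"{self.config.optimization_iterations} optimization iterations"
            )
        if self.config.stall_rule and len(self.hv_trail) >= 3:
            gains = []
            for a, b in zip(self.hv_trail[-3:-1], self.hv_trail[-2:]):
                gains.append((b - a) / a if a > 0 else np.inf)
            if all(g < self.config.stall_tol for g in gains):
                return True, (
                    f"stall: relative hypervolume gain below {self.config.stall_tol} "
                    "for 2 consecutive iterations"
                )
        return False, f"continue: at iteration {self.iteration}"

    # --------------------------------------------------------------- report
    def report(self, plots: bool = True) -> dict:
        """Per-iteration distributions, Pareto front, hypervolume trail.

        Pure function of the stored observations (never mutates state); the
        JSON written to the campaign directory is canonicalized so repeated
        reports are bit-identical.
        """
        done = self._completed()
        if done.empty:
            raise CampaignError("no completed observations to report")
        Y = done[list(OBJECTIVE_COLUMNS)].to_numpy(dtype=float)
        front_mask = pareto.pareto_mask(Y)
        hv = pareto.hypervolume_2d(Y[front_mask], self.config.reference_point)

        def five_number(series) -> dict:
            q = np.percentile(series.to_numpy(dtype=float), [0, 25, 50, 75, 100])
            return {
                "min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
                "q3": float(q[3]), "max": float(q[4]),
            }

        per_iteration = {}
        for it, grp in done.groupby("iteration"):
            per_iteration[str(int(it))] = {
                "n": int(len(grp)),
                "parameters": {c: five_number(grp[c]) for c in PARAM_COLUMNS},
                "objectives": {c: five_number(grp[c]) for c in OBJECTIVE_COLUMNS},
            }

        # suggested single record: normalized objective sum minus a small
        # normalized-nutrient-cost penalty; the Pareto set stays authoritative
        obj_lo = np.array([o.min_value for o in self.objectives])
        obj_hi = np.array([o.max_value for o in self.objectives])
        y_norm = (Y - obj_lo) / (obj_hi - obj_lo)
        nutrients = done[list(PARAM_COLUMNS[:4])].to_numpy(dtype=float)
        lo, hi = self.space.lower[:4], self.space.upper[:4]
        cost = np.mean((nutrients - lo) / (hi - lo), axis=1)
        score = y_norm.sum(axis=1) - 0.1 * cost
        best_idx = int(np.argmax(score))

        report = {
            "iterations_completed": self.iteration,
            "n_completed": int(len(done)),
            "per_iteration": per_iteration,
            "pareto_front": {
                "experiment_ids": done.loc[front_mask, "experiment_id"].tolist(),
                "objectives": Y[front_mask].tolist(),
            },
            "hypervolume": hv,
            "hypervolume_trail": list(self.hv_trail),
            "reference_point": list(self.config.reference_point),
            "best_observed_suggestion": {
                "experiment_id": done.iloc[best_idx]["experiment_id"],
                "scalarization": "sum of range-normalized objectives minus "
                "0.1 x mean normalized nutrient concentration",
                "score": float(score[best_idx]),
                "x": done.iloc[best_idx][list(PARAM_COLUMNS)].astype(float).tolist(),
                "y": Y[best_idx].tolist(),
            },
        }
        canonical = json.dumps(report, sort_keys=True, separators=(",", ":"), allow_nan=False)
        with open(self.dir / "report.json", "w", encoding="utf-8") as fh:
            fh.write(canonical)
        if plots:
            self._plot_report(done, front_mask)
        return report

    def _plot_report(self, done: pd.DataFrame, front_mask: np.ndarray) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        iterations = sorted(done["iteration"].astype(int).unique())
        fig, axes = plt.subplots(1, 5, figsize=(18, 3.2))
        for ax, col in zip(axes, PARAM_COLUMNS):
            data = [done.loc[done["iteration"] == it, col].to_numpy(dtype=float) for it in iterations]
            ax.boxplot(data, tick_labels=[str(i) for i in iterations])
            ax.set_title(col)
            ax.set_xlabel("iteration")
        fig.tight_layout()
        fig.savefig(self.dir / "report_parameters.png", dpi=110)
        plt.close(fig)

        fig, (ax1, ax2, ax3) = plt.subplots(1, 3, figsize=(12, 3.4))
        for ax, col in ((ax1, OBJECTIVE_COLUMNS[0]), (ax2, OBJECTIVE_COLUMNS[1])):
            data = [done.loc[done["iteration"] == it, col].to_numpy(dtype=float) for it in iterations]
            ax.boxplot(data, tick_labels=[str(i) for i in iterations])
            ax.set_title(col)
            ax.set_xlabel("iteration")
        Y = done[list(OBJECTIVE_COLUMNS)].to_numpy(dtype=float)
        ax3.scatter(Y[:, 0], Y[:, 1], s=18, c="0.6", label="observed")
        ax3.scatter(Y[front_mask, 0], Y[front_mask, 1], s=30, c="C3", label="Pareto front")
        ax3.set_xlabel("final FM (g/L)")
        ax3.set_ylabel("FM increase (g/(L·h))")
        ax3.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(self.dir / "report_objectives.png", dpi=110)
        plt.close(fig)

    # ------------------------------------------------------------ closed loop
    def run(
        self,
        sim_params: simulator.SimulatorParams | None = None,
        iterations: int | None = None,
        noise: bool = True,
    ) -> dict:
        """Closed loop against the bundled fermentation oracle."""
        p = sim_params or simulator.SimulatorParams()
        budget = iterations or self.config.optimization_iterations
        while self.iteration < budget:
            stop, reason = self.check_termination()
            if stop:
                log.info("terminating: %s", reason)
                break
            self.propose()
            t_next = self.iteration + 1
            pending = self.obs[self.obs["status"] == "proposed"]
            filled = simulator.simulate_sheet(
                pending, p, seed=_derived_seed(self.config.seed, t_next, 999), noise=noise
            )
            self.ingest(filled[["experiment_id", *OBJECTIVE_COLUMNS, "status"]])
        return self.report(plots=False)


def init_campaign(historical_sheet, config: CampaignConfig, directory) -> Campaign:
    """Functional alias for :meth:`Campaign.init`."""
    return Campaign.init(historical_sheet, config, directory)
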