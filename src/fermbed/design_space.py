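"""Bounded design and objective spaces for fermentation-medium optimization.

The default space is the five controllable parameters of a BY-2 batch
fermentation (four macronutrients plus the inoculum density), each with box
bounds in physical units, and a bi-objective maximization space (final fresh
mass and fresh-mass increase).  Internally all modelling happens on the unit
cube; this module owns the affine normalization and quasi-random sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy.stats import qmc

__all__ = [
    "ParameterSpec",
    "ObjectiveSpec",
    "DesignSpace",
    "DesignSpaceError",
    "default_design_space",
    "default_objectives",
    "normalize",
    "denormalize",
    "sobol_design",
    "validate_observation",
]

#: exact CSV sheet column names, in design-space order
PARAM_COLUMNS = (
    "sucrose_mM",
    "ammonium_mM",
    "phosphate_mM",
    "nitrate_mM",
    "start_fm_g_L",
)
OBJECTIVE_COLUMNS = ("final_fm_g_L", "fm_increase_g_L_h")
SHEET_COLUMNS = (
    "experiment_id",
    "iteration",
    *PARAM_COLUMNS,
    *OBJECTIVE_COLUMNS,
    "status",
)


class DesignSpaceError(ValueError):
    """Raised for invalid parameter definitions, dimensions or bounds."""


@dataclass(frozen=True)
class ParameterSpec:
    """One bounded continuous design parameter."""

    name: str
    unit: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.unit:
            raise DesignSpaceError(f"parameter {self.name!r}: unit must be nonempty")
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise DesignSpaceError(f"parameter {self.name!r}: bounds must be finite")
        if not self.lower < self.upper:
            raise DesignSpaceError(
                f"parameter {self.name!r}: lower ({self.lower}) must be < upper ({self.upper})"
            )


@dataclass(frozen=True)
class ObjectiveSpec:
    """One objective with its physical range; both campaign objectives maximize."""

    name: str
    unit: str
    min_value: float
    max_value: float
    direction: str = "maximize"

    def __post_init__(self) -> None:
        if not self.min_value < self.max_value:
            raise DesignSpaceError(
                f"objective {self.name!r}: min_value must be < max_value"
            )
        if self.direction != "maximize":
            raise DesignSpaceError(
                f"objective {self.name!r}: only maximization is supported"
            )


@dataclass(frozen=True)
class DesignSpace:
    """Ordered collection of :class:`ParameterSpec` spanning a box in R^n."""

    params: tuple[ParameterSpec, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise DesignSpaceError("parameter names must be unique")

    @property
    def dimension(self) -> int:
        return len(self.params)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    @property
    def lower(self) -> np.ndarray:
        return np.array([p.lower for p in self.params], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([p.upper for p in self.params], dtype=float)

    def to_dict(self) -> dict:
        return {
            "parameters": [
                {"name": p.name, "unit": p.unit, "lower": p.lower, "upper": p.upper}
                for p in self.params
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpace":
        return cls(
            tuple(
                ParameterSpec(e["name"], e["unit"], float(e["lower"]), float(e["upper"]))
                for e in d["parameters"]
            )
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DesignSpace":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_design_space() -> DesignSpace:
    """The standard 5-D medium/inoculum space (order fixed)."""
    return DesignSpace(
        (
            ParameterSpec("sucrose", "mM", 20.0, 175.0),
            ParameterSpec("ammonium", "mM", 5.0, 60.0),
            ParameterSpec("phosphate", "mM", 2.0, 15.0),
            ParameterSpec("nitrate", "mM", 5.0, 150.0),
            ParameterSpec("start_fm", "g/L", 5.0, 22.0),
        )
    )


def default_objectives() -> tuple[ObjectiveSpec, ObjectiveSpec]:
    """Final fresh mass and fresh-mass increase, both maximized."""
    return (
        ObjectiveSpec("final_fm", "g/L", 0.0, 200.0),
        ObjectiveSpec("fm_increase", "g/(L×h)", 0.0, 25.0),
    )


def objectives_to_dict(objectives: Sequence[ObjectiveSpec]) -> dict:
    return {
        "objectives": [
            {
                "name": o.name,
                "unit": o.unit,
                "min_value": o.min_value,
                "max_value": o.max_value,
                "direction": o.direction,
            }
            for o in objectives
        ]
    }


def objectives_from_dict(d: dict) -> tuple[ObjectiveSpec, ...]:
    return tuple(
        ObjectiveSpec(
            e["name"], e["unit"], float(e["min_value"]), float(e["max_value"]), e["direction"]
        )
        for e in d["objectives"]
    )


def _as_matrix(x, n: int, what: str) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    was_1d = arr.ndim == 1
    if was_1d:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != n:
        raise DesignSpaceError(
            f"{what}: expected vectors of dimension {n}, got shape {arr.shape}"
        )
    return arr, was_1d


def normalize(x_physical, space: DesignSpace, *, rtol: float = 1e-9) -> np.ndarray:
    """Affine map from physical units onto the unit cube.

    Accepts a single vector or a (k, n) matrix; returns the same shape.
    Coordinates outside the bounds beyond ``rtol`` (relative to the span)
    raise a validation error naming the offending parameter.
    """
    arr, was_1d = _as_matrix(x_physical, space.dimension, "normalize")
    lo, hi = space.lower, space.upper
    span = hi - lo
    u = (arr - lo) / span
    tol = rtol
    for j, p in enumerate(space.params):
        bad = (u[:, j] < -tol) | (u[:, j] > 1.0 + tol)
        if np.any(bad):
            val = arr[np.argmax(bad), j]
            raise DesignSpaceError(
                f"parameter {p.name!r}: value {val} outside bounds [{p.lower}, {p.upper}]"
            )
    u = np.clip(u, 0.0, 1.0)
    return u[0] if was_1d else u


def denormalize(u, space: DesignSpace) -> np.ndarray:
    """Inverse of :func:`normalize` (unit cube to physical units)."""
    arr, was_1d = _as_matrix(u, space.dimension, "denormalize")
    if np.any(arr < -1e-12) or np.any(arr > 1.0 + 1e-12):
        raise DesignSpaceError("denormalize: coordinates must lie in [0, 1]")
    x = space.lower + np.clip(arr, 0.0, 1.0) * (space.upper - space.lower)
    return x[0] if was_1d else x


def sobol_design(space: DesignSpace, n_points: int, seed: int) -> np.ndarray:
    """Scrambled Sobol' design of ``n_points`` in physical units.

    Deterministic for a fixed seed; points are pairwise distinct with
    probability one thanks to Owen scrambling.
    """
    if n_points < 1:
        raise DesignSpaceError("sobol_design: n_points must be >= 1")
    sampler = qmc.Sobol(d=space.dimension, scramble=True, rng=np.random.default_rng(seed))
    m = max(0, int(np.ceil(np.log2(n_points))))
    u = sampler.random_base2(m)[:n_points]
    return denormalize(u, space)


def validate_observation(
    x, y, space: DesignSpace, objectives: Sequence[ObjectiveSpec]
) -> list[dict]:
    """Flag (but do not reject) out-of-bounds parameters / objective values.

    Returns a list of violation records; empty when everything is in range.
    Historical sheets may legitimately sit at or beyond bounds, so callers
    should warn on a nonempty report rather than drop the record.
    """
    try:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    except (TypeError, ValueError) as exc:
        raise DesignSpaceError(f"non-numeric observation entry: {exc}") from exc
    if xv.shape != (space.dimension,):
        raise DesignSpaceError(
            f"validate_observation: x must have dimension {space.dimension}"
        )
    if yv.shape != (len(objectives),):
        raise DesignSpaceError(
            f"validate_observation: y must have dimension {len(objectives)}"
        )
    report: list[dict] = []
    for p, v in zip(space.params, xv):
        if not np.isfinite(v):
            report.append({"name": p.name, "value": float(v), "bound": None, "kind": "non-finite"})
        elif v < p.lower:
            report.append({"name": p.name, "value": float(v), "bound": p.lower, "kind": "below"})
        elif v > p.upper:
            report.append({"name": p.name, "value": float(v), "bound": p.upper, "kind": "above"})
    for o, v in zip(objectives, yv):
        if not np.isfinite(v):
            report.append({"name": o.name, "value": float(v), "bound": None, "kind": "non-finite"})
        elif v < o.min_value:
            report.append({"name": o.name, "value": float(v), "bound": o.min_value, "kind": "below"})
        elif v > o.max_value:
            report.append({"name": o.name, "value": float(v), "bound": o.max_value, "kind": "above"})
    return report
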