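"""Pareto dominance and exact bi-objective hypervolume under maximization.

All routines follow the maximization convention throughout: a point dominates
another if it is at least as good in every objective and strictly better in at
least one, and the hypervolume is the area of objective space dominated by the
front and bounded below by the reference point.  Points on or below the
reference boundary contribute zero area (half-open dominated region), so the
hypervolume improvement is always nonnegative.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dominates",
    "pareto_mask",
    "pareto_front",
    "hypervolume_2d",
    "hypervolume_improvement",
    "hypervolume_2d_batch",
]


def _check_dim(Y: np.ndarray, m: int | None = None) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.ndim != 2:
        raise ValueError("objective vectors must form a 2-D array")
    if m is not None and Y.shape[1] != m:
        raise ValueError(f"expected {m} objectives, got {Y.shape[1]}")
    if not np.all(np.isfinite(Y)):
        raise ValueError("objective vectors must be finite")
    return Y


def dominates(a, b) -> bool:
    """True iff ``a`` Pareto-dominates ``b`` (maximization)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return bool(np.all(a >= b) and np.any(a > b))

def pareto_mask(Y) -> np.ndarray:
    """Boolean mask of nondominated rows of ``Y`` (duplicates: first kept)."""
    Y = _check_dim(Y)
    n = Y.shape[0]
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        if not mask[i]:
            continue
        geq = np.all(Y >= Y[i], axis=1)
        gt = np.any(Y > Y[i], axis=1)
        dominated_by = geq & gt
        dominated_by[i] = False
        if np.any(dominated_by & mask):
            mask[i] = False
            continue
        # drop later exact duplicates of a surviving point
        dup = np.all(Y == Y[i], axis=1)
        dup[: i + 1] = False
        mask[dup] = False
    return mask


def pareto_front(Y) -> np.ndarray:
    """The nondominated subset of ``Y``, in input order."""
    Y = _check_dim(Y)
    return Y[pareto_mask(Y)]


def hypervolume_2d(front, reference_point) -> float:
    """Exact dominated area for two maximized objectives.

    Sorts on the first objective and sums the disjoint staircase rectangles.
    Dominated or duplicate points are harmless; an empty front has volume 0.
    """
    ref = np.asarray(reference_point, dtype=float)
    if ref.shape != (2,):
        raise ValueError("reference_point must have 2 components")
    front = np.asarray(front, dtype=float)
    if front.size == 0:
        return 0.0
    front = _check_dim(front, m=2)
    keep = (front[:, 0] > ref[0]) & (front[:, 1] > ref[1])
    pts = front[keep]
    if pts.shape[0] == 0:
        return 0.0
    order = np.argsort(-pts[:, 0], kind="stable")
    pts = pts[order]
    c = np.maximum.accumulate(pts[:, 1])
    prev = np.concatenate(([ref[1]], c[:-1]))
    prev = np.maximum(prev, ref[1])
    widths = pts[:, 0] - ref[0]
    heights = np.maximum(c, ref[1]) - prev
    return float(np.sum(widths * heights))


def hypervolume_improvement(front, reference_point, candidates) -> float:
    """HV(front ∪ candidates) − HV(front); always ≥ 0."""
    front = np.asarray(front, dtype=float).reshape(-1, 2)
    cand = np.asarray(candidates, dtype=float).reshape(-1, 2)
    base = hypervolume_2d(front, reference_point)
    joint = hypervolume_2d(np.vstack([front, cand]) if front.size else cand, reference_point)
    return max(0.0, joint - base)


def hypervolume_2d_batch(Y: np.ndarray, reference_point) -> np.ndarray:
    """Vectorized exact 2-D hypervolume for a stack of point sets.

    ``Y`` has shape (batch, n_points, 2); returns shape (batch,).  Used by the
    Monte-Carlo acquisition, where each batch member is one posterior draw.
    """
    ref = np.asarray(reference_point, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 3 or Y.shape[-1] != 2:
        raise ValueError("expected shape (batch, n_points, 2)")
    y1 = np.maximum(Y[..., 0], ref[0])
    # mask points not above ref in the first objective by flooring their height
    y2 = np.where(Y[..., 0] > ref[0], Y[..., 1], ref[1])
    y2 = np.maximum(y2, ref[1])
    order = np.argsort(-y1, axis=1, kind="stable")
    y1s = np.take_along_axis(y1, order, axis=1)
    y2s = np.take_along_axis(y2, order, axis=1)
    c = np.maximum.accumulate(y2s, axis=1)
    prev = np.concatenate([np.full((Y.shape[0], 1), ref[1]), c[:, :-1]], axis=1)
    return np.sum((y1s - ref[0]) * (c - prev), axis=1)
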