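"""Polyhedral helpers for the outer-approximation MOLP solver."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import HalfspaceIntersection

from .errors import SolverError


def chebyshev_center(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and radius of the largest ball inside {y : A y <= b}."""
    norms = np.linalg.norm(A, axis=1)
    m, k = A.shape
    # variables (y, r): maximize r s.t. A y + ||a_i|| r <= b
    c = np.zeros(k + 1)
    c[-1] = -1.0
    A_ub = np.hstack([A, norms[:, None]])
    res = linprog(c, A_ub=A_ub, b_ub=b, bounds=[(None, None)] * k + [(0, None)],
                  method="highs")
    if res.status != 0:
        raise SolverError("Chebyshev-center LP failed; outer polytope degenerate")
    return res.x[:k], res.x[-1]


def polytope_vertices(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vertices of the bounded polytope {y : A y <= b} (dimension >= 2)."""
    center, radius = chebyshev_center(A, b)
    if radius <= 1e-12:
        # flat polytope: fall back to pairwise/triple plane intersections
        return _vertices_by_enumeration(A, b)
    hs = HalfspaceIntersection(np.hstack([A, -b[:, None]]), center)
    verts = np.asarray(hs.intersections)
    return _dedupe(verts)


def _vertices_by_enumeration(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    from itertools import combinations

    k = A.shape[1]
    out = []
    for idx in combinations(range(A.shape[0]), k):
        M = A[list(idx)]
        if abs(np.linalg.det(M)) < 1e-12:
            continue
        y = np.linalg.solve(M, b[list(idx)])
        if np.all(A @ y <= b + 1e-8):
            out.append(y)
    if not out:
        raise SolverError("empty outer polytope")
    return _dedupe(np.array(out))


def _dedupe(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Merge points equal within tol, lexicographically sorted."""
    if len(points) == 0:
        return points
    order = np.lexsort(points.T[::-1])
    points = points[order]
    keep = [points[0]]
    for p in points[1:]:
        if np.max(np.abs(p - keep[-1])) > tol:
            keep.append(p)
    return np.array(keep)


def dedupe_tol(points: np.ndarray, tol: float) -> np.ndarray:
    """Componentwise-tolerance dedup with lexicographic tie-breaking.

    Unlike :func:`_dedupe` this merges clusters transitively: points within
    tol of an already-kept representative are dropped.
    """
    if len(points) == 0:
        return points
    order = np.lexsort(points.T[::-1])
    points = points[order]
    kept: list[np.ndarray] = []
    for p in points:
        if all(np.max(np.abs(p - q)) > tol for q in kept):
            kept.append(p)
    return np.array(kept)
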