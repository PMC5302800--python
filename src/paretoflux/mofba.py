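"""Multi-objective flux balance analysis (MO-FBA).

Each of the k community members keeps its own growth objective; the solution
of the resulting multi-objective LP is not a single value but the *Pareto
front* -- the set of non-dominated points of the image {C'v : v feasible} in
objective space.  Because the problem is a MOLP, the front is a piece of the
boundary of a convex polyhedron and admits an exact vertex/facet description.

:func:`solve_mofba` computes that description with a primal Benson-type outer
approximation: starting from the box of per-objective optima it repeatedly
(i) enumerates the vertices of the current outer polytope, (ii) measures how
far each vertex sits above the attainable image along the all-ones direction,
and (iii) cuts with the supporting hyperplane recovered from the LP duals of
the worst vertex, until every outer vertex is attainable within tolerance.
The weighted-sum and epsilon-constraint scalarizations are provided both as
analysis tools and as independent oracles for the front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import dedupe_tol, polytope_vertices
from .community import CommunityModel
from .errors import InfeasibleError, SolverError, UnboundedObjectiveError, ValidationError
from .lp import compile_lp, solve_max

#: vertex deduplication / attainability tolerance
DEFAULT_TOL = 1e-6


@dataclass
class ParetoFront:
    """Vertices, rays and facet inequalities of the image of efficient points.

    ``facets`` are pairs (normal, offset) with non-negative normals, meaning
    ``normal . f <= offset`` for every attainable objective vector f; each is
    supporting (tight at >= 1 vertex).  ``efficient_points`` holds, for each
    vertex, one feasible community flux vector attaining it.
    """

    k: int
    vertices: np.ndarray                      # (m, k)
    rays: list[np.ndarray] = field(default_factory=list)
    facets: list[tuple[np.ndarray, float]] = field(default_factory=list)
    efficient_points: list[np.ndarray] = field(default_factory=list)

    def contains(self, point: np.ndarray, tol: float = DEFAULT_TOL) -> bool:
        """Point satisfies every facet inequality within tol."""
        p = np.asarray(point, dtype=float)
        return all(w @ p <= off + tol for w, off in self.facets)

    def on_boundary(self, point: np.ndarray, tol: float = DEFAULT_TOL) -> bool:
        p = np.asarray(point, dtype=float)
        return self.contains(p, tol) and any(
            abs(w @ p - off) <= tol * max(1.0, abs(off)) for w, off in self.facets
        )

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "vertices": self.vertices.tolist(),
            "rays": [r.tolist() for r in self.rays],
            "facets": [{"normal": w.tolist(), "offset": off} for w, off in self.facets],
        }


def _feasibility_gap(y: np.ndarray, lp, C: np.ndarray):
    """min t s.t. C'v >= y - t*1, v feasible.

    t* <= 0 means y is attainable (dominated by some feasible image point).
    Returns (t*, v*, w) where w are the non-negative duals of the objective
    rows -- the normal of a supporting hyperplane when t* > 0.
    """
    k = C.shape[1]
    n = lp.n
    # variables (v, t); rows: -C'v - t*1 <= -y
    A_ub_obj = np.hstack([-C.T, -np.ones((k, 1))])
    A_ub = np.hstack([lp.A_ub, np.zeros((lp.A_ub.shape[0], 1))])
    A_ub = np.vstack([A_ub_obj, A_ub])
    b_ub = np.concatenate([-y, lp.b_ub])
    A_eq = np.hstack([lp.A_eq, np.zeros((lp.A_eq.shape[0], 1))])
    from scipy.optimize import linprog

    c = np.zeros(n + 1)
    c[-1] = 1.0
    res = linprog(
        c,
        A_ub=A_ub, b_ub=b_ub,
        A_eq=A_eq if A_eq.size else None,
        b_eq=lp.b_eq if A_eq.size else None,
        bounds=[(lo, hi) for lo, hi in zip(lp.lb, lp.ub)] + [(None, None)],
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError("community model is infeasible")
    if res.status != 0:
        raise SolverError(f"feasibility LP failed (status {res.status})")
    t_star = res.fun
    v_star = res.x[:n]
    w = -np.asarray(res.ineqlin.marginals[:k])
    w = np.clip(w, 0.0, None)
    s = w.sum()
    w = w / s if s > 1e-12 else np.ones(k) / k
    return t_star, v_star, w


def solve_mofba(
    community: CommunityModel,
    tol: float = DEFAULT_TOL,
    max_iter: int = 500,
) -> ParetoFront:
    """Exact vertex/facet description of the Pareto front of per-strain growth.

    Raises :class:`UnboundedObjectiveError` naming the strain if any single
    objective is unbounded, and :class:`InfeasibleError` if the model has no
    feasible flux vector.
    """
    community.validate()
    lp = compile_lp(community)
    C = community.objective_matrix()
    k = community.k

    # per-objective extrema: ideal values (upper box) and artificial floors
    ideal = np.zeros(k)
    floor = np.zeros(k)
    for j, strain in enumerate(community.strains):
        hi = solve_max(C[:, j], lp)
        if hi.status == "unbounded":
            raise UnboundedObjectiveError(
                f"objective of strain {strain.id!r} is unbounded"
            )
        if hi.status == "infeasible":
            raise InfeasibleError("community model is infeasible")
        if not hi.optimal:
            raise SolverError(f"FBA for strain {strain.id!r} failed: {hi.status}")
        lo = solve_max(-C[:, j], lp)
        if not lo.optimal:
            raise SolverError(f"objective floor LP for {strain.id!r}: {lo.status}")
        ideal[j] = hi.objective
        floor[j] = -lo.objective

    if k == 1:
        y = np.array([ideal[0]])
        _, v_star, _ = _feasibility_gap(y, lp, C)
        return ParetoFront(
            k=1,
            vertices=y[None, :],
            facets=[(np.array([1.0]), ideal[0])],
            efficient_points=[v_star],
        )

    # artificial lower bounds strictly below the attainable image, so genuine
    # vertices never touch them
    margin = np.maximum(1.0, 0.1 * (ideal - floor))
    lower = floor - margin

    halfspaces: list[tuple[np.ndarray, float]] = []
    for j in range(k):
        e = np.zeros(k)
        e[j] = 1.0
        halfspaces.append((e.copy(), ideal[j]))
        halfspaces.append((-e.copy(), -lower[j]))

    verified: dict[tuple, np.ndarray] = {}  # rounded vertex -> attaining v

    def key(y):
        return tuple(np.round(y / (0.1 * tol)).astype(np.int64))

    gap_tol = 0.1 * tol
    for _ in range(max_iter):
        A = np.array([w for w, _ in halfspaces])
        b = np.array([off for _, off in halfspaces])
        verts = polytope_vertices(A, b)
        worst = None
        for y in verts:
            if key(y) in verified:
                continue
            t_star, v_star, w = _feasibility_gap(y, lp, C)
            if t_star <= gap_tol:
                verified[key(y)] = v_star
            elif worst is None or t_star > worst[0]:
                worst = (t_star, y, w)
        if worst is None:
            break
        _, _, w = worst
        sup = solve_max(C @ w, lp)
        if not sup.optimal:
            raise SolverError(f"weighted-sum LP failed: {sup.status}")
        halfspaces.append((w, sup.objective))
    else:
        raise SolverError(
            f"Benson outer approximation did not converge in {max_iter} cuts"
        )

    # polish outer vertices to attained image points and drop the artificial box
    final = []
    efficient = []
    for y in verts:
        if np.any(y <= lower + 10 * tol):
            continue
        v_star = verified.get(key(y))
        if v_star is None:
            _, v_star, _ = _feasibility_gap(y, lp, C)
        p = C.T @ v_star
        # squash solver noise only; anything >= 1e-9 is a real coordinate
        final.append(np.where(np.abs(p) < 1e-9, 0.0, p))
        efficient.append(v_star)
    pts = dedupe_tol(np.array(final), tol)
    # map attained flux vectors back to the deduped vertex order
    eff = []
    for p in pts:
        i = int(np.argmin([np.max(np.abs(p - q)) for q in final]))
        eff.append(efficient[i])

    facets = _supporting_facets(halfspaces, pts, lower, tol)
    return ParetoFront(k=k, vertices=pts, facets=facets, efficient_points=eff)


def _supporting_facets(halfspaces, vertices, lower, tol):
    """Facets of the efficient image: non-artificial halfspaces tight at
    enough vertices to carry a (k-1)-dimensional face; normalized, deduped."""
    facets = []
    if not len(vertices):
        return facets
    k = vertices.shape[1]
    need = min(k, len(vertices))
    for w, off in halfspaces:
        if np.any(w < -tol):  # artificial lower bound
            continue
        vals = vertices @ w
        n_tight = int(np.sum(np.abs(vals - off) <= tol * max(1.0, abs(off))))
        if n_tight < need:
            continue
        if abs(off) > tol:
            w, off = w / abs(off), np.sign(off) * 1.0
        else:
            nrm = np.linalg.norm(w)
            w, off = w / nrm, off / nrm
        if not any(
            np.max(np.abs(w - w2)) <= 1e-7 and abs(off - off2) <= 1e-7
            for w2, off2 in facets
        ):
            facets.append((w, off))
    return facets


def weighted_sum(community: CommunityModel, weights) -> np.ndarray:
    """Maximize the weighted sum of strain objectives; returns the image point.

    Weights must be non-negative with at least one positive entry.  The
    returned point is Pareto-optimal for every valid weight vector: for
    strictly positive weights this follows from convexity of the MOLP, and
    for weights with zero entries a second stage maximizes the plain sum of
    objectives over the first-stage optimal face, discarding the weakly
    efficient (dominated) alternatives.
    """
    lam = np.asarray(weights, dtype=float)
    if lam.shape != (community.k,):
        raise ValidationError(
            f"expected {community.k} weights, got shape {lam.shape}"
        )
    if np.any(lam < 0) or not np.any(lam > 0):
        raise ValidationError("weights must be >= 0 with at least one > 0")
    lp = compile_lp(community)
    C = community.objective_matrix()
    c1 = C @ lam
    sol = solve_max(c1, lp)
    if sol.status == "unbounded":
        raise UnboundedObjectiveError("weighted-sum objective is unbounded")
    if not sol.optimal:
        raise SolverError(f"weighted-sum LP is {sol.status}", status=sol.status)
    if np.all(lam > 0):
        return C.T @ sol.x
    # zero weights: refine within the optimal face to an efficient point
    z1 = sol.objective
    # slack only absorbs the solver's objective round-off; a larger slack
    # would let the refinement drift off the optimal face along shallow edges
    slack = 1e-12 * max(1.0, abs(z1))
    refined = lp.with_rows(A_ub=-c1, b_ub=-(z1 - slack))
    sol2 = solve_max(C.sum(axis=1), refined)
    if not sol2.optimal:
        return C.T @ sol.x
    return C.T @ sol2.x


def epsilon_constraint(
    community: CommunityModel, j: int, floors
) -> np.ndarray:
    """Maximize objective j subject to f_i >= floors[i] for i != j.

    ``floors`` is a length-k sequence whose j-th entry is ignored.  The result
    is a weakly efficient point; infeasible floors raise
    :class:`InfeasibleError`.
    """
    eps = np.asarray(floors, dtype=float)
    if eps.shape != (community.k,):
        raise ValidationError(
            f"expected {community.k} floors (entry {j} ignored), got {eps.shape}"
        )
    lp = compile_lp(community)
    C = community.objective_matrix()
    others = [i for i in range(community.k) if i != j]
    if others:
        lp = lp.with_rows(
            A_ub=-C[:, others].T,
            b_ub=-eps[others],
        )
    sol = solve_max(C[:, j], lp)
    if sol.status == "infeasible":
        raise InfeasibleError(
            f"epsilon-constraint floors {eps[others].tolist()} are infeasible"
        )
    if sol.status == "unbounded":
        raise UnboundedObjectiveError(
            f"objective {j} is unbounded under the given floors"
        )
    if not sol.optimal:
        raise SolverError(f"epsilon-constraint LP is {sol.status}")
    return C.T @ sol.x


@dataclass
class FrontVerification:
    n_samples: int
    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_front(
    front: ParetoFront,
    community: CommunityModel,
    n_samples: int = 100,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
) -> FrontVerification:
    """Cross-check a computed front against weighted-sum scalarization.

    Draws random strictly positive weight vectors, solves each weighted-sum
    LP, and asserts that every solution lies on the front boundary and that no
    solution dominates any front vertex.
    """
    rng = np.random.default_rng(seed)
    report = FrontVerification(n_samples=n_samples)
    for _ in range(n_samples):
        lam = rng.dirichlet(np.ones(front.k))
        lam = np.clip(lam, 1e-6, None)
        y = weighted_sum(community, lam)
        if not front.on_boundary(y, tol):
            report.violations.append(
                {"weights": lam.tolist(), "point": y.tolist(),
                 "reason": "weighted-sum solution off the front boundary"}
            )
        for v in front.vertices:
            if np.all(y >= v - tol) and np.any(y > v + tol):
                report.violations.append(
                    {"weights": lam.tolist(), "point": y.tolist(),
                     "reason": f"dominates vertex {v.tolist()}"}
                )
    return report
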