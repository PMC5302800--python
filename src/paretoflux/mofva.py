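"""Multi-objective flux variability analysis (MO-FVA).

Near a chosen Pareto point f*, the flux range of every reaction is obtained
by minimizing/maximizing v_j subject to the community constraints plus the
componentwise fraction-of-optimum constraint ``C'v >= alpha * f*`` -- each
strain keeps at least the fraction ``alpha`` of its growth rate at f*.

For three-member communities the front spanned by three anchor vertices is
swept with a barycentric lattice (``(n+1)(n+2)/2`` points for ``n``
subdivisions); per-point ranges can then be averaged over ``r^2`` congruent
triangular regions for summarizing large meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import CommunityModel
from .errors import InfeasibleError, SolverError, ValidationError
from .fba import FluxRangeSet
from .lp import compile_lp, solve_max
from .mofba import ParetoFront, epsilon_constraint

DEFAULT_ALPHA = 0.9  # fraction of optimum used throughout the case study


def mofva_at_point(
    community: CommunityModel,
    f_star,
    alpha: float = DEFAULT_ALPHA,
    reactions: list[str] | None = None,
) -> FluxRangeSet:
    """Flux ranges subject to C'v >= alpha * f* (componentwise).

    A zero component of f* makes that strain's floor vacuous.  If alpha * f*
    lies strictly above the front the base problem is infeasible and an
    :class:`InfeasibleError` is raised.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    f_star = np.asarray(f_star, dtype=float)
    if f_star.shape != (community.k,):
        raise ValidationError(
            f"f_star must have length {community.k}, got shape {f_star.shape}"
        )
    lp = compile_lp(community)
    C = community.objective_matrix()
    lp = lp.with_rows(A_ub=-C.T, b_ub=-alpha * f_star)

    names = lp.names
    wanted = names if reactions is None else list(reactions)
    idx = {nm: i for i, nm in enumerate(names)}
    ranges: dict[str, tuple[float, float]] = {}
    e = np.zeros(lp.n)
    first = True
    for rid in wanted:
        j = idx[rid]
        e[:] = 0.0
        e[j] = 1.0
        hi = solve_max(e, lp)
        if first and hi.status == "infeasible":
            raise InfeasibleError(
                f"objective floors alpha*f* = {(alpha * f_star).tolist()} are "
                "infeasible (point above the Pareto front)"
            )
        first = False
        lo = solve_max(-e, lp)
        if not (hi.optimal and lo.optimal):
            bad = hi if not hi.optimal else lo
            raise SolverError(f"MO-FVA subproblem for {rid} is {bad.status}",
                              status=bad.status)
        vmin, vmax = -lo.objective, hi.objective
        if vmin > vmax:
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rid] = (vmin, vmax)
    return FluxRangeSet(alpha=alpha, ranges=ranges, reference=f_star)


# ---------------------------------------------------------------------------
# barycentric meshing of a triangular front face


@dataclass
class ParetoMesh:
    """Barycentric lattice over the triangle spanned by three anchor vertices.

    ``points`` holds (weights, f_star) pairs: the barycentric weights
    (non-negative, summing to 1) and the objective-space point they map to.
    """

    anchors: np.ndarray                 # (3, k) anchor vertices
    n: int                              # subdivisions per edge
    points: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __len__(self):
        return len(self.points)


def mesh_front(
    front: ParetoFront,
    anchors: tuple[int, int, int] = (0, 1, 2),
    n: int = 100,
    community: CommunityModel | None = None,
    lift: str = "flat",
) -> ParetoMesh:
    """Equally distributed points on the front face spanned by three anchors.

    ``anchors`` indexes three vertices of ``front`` (three-objective
    communities only).  Lattice points sit at barycentric combinations
    (i/n, j/n, (n-i-j)/n).  With ``lift="flat"`` (default) each point is the
    plain convex combination of the anchors -- on or below the front, which
    is what the alpha-scaled MO-FVA floors require.  With ``lift="epsilon"``
    each point is pushed onto the Pareto surface by an epsilon-constraint LP
    maximizing the largest-weight objective subject to the other floors
    (requires ``community``).
    """
    if front.k != 3:
        raise ValidationError(
            f"front meshing supports exactly 3 objectives, got k={front.k}"
        )
    if n < 1:
        raise ValidationError("n must be >= 1")
    if lift not in ("flat", "epsilon"):
        raise ValidationError(f"unknown lift mode {lift!r}")
    if lift == "epsilon" and community is None:
        raise ValidationError("epsilon lift requires the community model")
    A = np.array([front.vertices[i] for i in anchors], dtype=float)
    mesh = ParetoMesh(anchors=A, n=n)
    for i in range(n + 1):
        for j in range(n + 1 - i):
            w = np.array([i, j, n - i - j], dtype=float) / n
            flat = w @ A
            if lift == "flat":
                point = flat
            else:
                jmax = int(np.argmax(w))
                point = epsilon_constraint(community, jmax, flat)
            mesh.points.append((w, point))
    return mesh


def mesh_points_array(mesh: ParetoMesh) -> np.ndarray:
    return np.array([p for _, p in mesh.points])


# ---------------------------------------------------------------------------
# regional aggregation


def assign_regions(mesh: ParetoMesh, r: int) -> list[tuple[int, int, int, int]]:
    """Region key for every mesh point; r^2 congruent triangles partition the
    face.

    Scaling the barycentric weights by r and taking floors identifies the
    sub-triangle: floor sums of r-1 select an upward triangle, r-2 a downward
    one.  Lattice points on sub-triangle boundaries are assigned
    deterministically by an infinitesimal pull toward the centroid.
    """
    if r < 1:
        raise ValidationError("regional resolution r must be >= 1")
    keys = []
    third = np.array([1 / 3, 1 / 3, 1 / 3])
    for w, _ in mesh.points:
        ww = w * (1 - 1e-9) + 1e-9 * third  # strict interior of its cell
        f = ww * r
        a = np.floor(f).astype(int)
        s = int(a.sum())
        if s == r - 1:
            keys.append((a[0], a[1], a[2], 0))      # upward triangle
        elif s == r - 2:
            keys.append((a[0], a[1], a[2], 1))      # downward triangle
        else:  # exactly on a lattice vertex after the nudge; clamp to upward
            over = s - (r - 1)
            a[np.argmax(f - a)] -= over
            keys.append((a[0], a[1], a[2], 0))
    return keys


@dataclass
class RegionAggregate:
    """Per-region mean of member-point MO-FVA maxima and minima."""

    region: tuple[int, int, int, int]
    members: list[int]
    mean_min: dict[str, float]
    mean_max: dict[str, float]


def aggregate_regions(
    mesh: ParetoMesh,
    results: list[FluxRangeSet],
    r: int,
) -> list[RegionAggregate]:
    """Average per-point flux ranges over r^2 triangular regions.

    Every region must contain at least one mesh point; otherwise the
    resolution is incompatible with the mesh and a ValidationError is raised.
    """
    if len(results) != len(mesh.points):
        raise ValidationError(
            f"expected one FluxRangeSet per mesh point "
            f"({len(mesh.points)}), got {len(results)}"
        )
    keys = assign_regions(mesh, r)
    members: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        members.setdefault(key, []).append(i)
    if len(members) < r * r:
        raise ValidationError(
            f"regional resolution r={r} leaves {r * r - len(members)} of "
            f"{r * r} regions empty for a mesh with n={mesh.n}"
        )
    rids = list(results[0].ranges)
    out = []
    for key in sorted(members):
        idxs = members[key]
        mean_min = {}
        mean_max = {}
        for rid in rids:
            los = [results[i].ranges[rid][0] for i in idxs]
            his = [results[i].ranges[rid][1] for i in idxs]
            mean_min[rid] = float(np.mean(los))
            mean_max[rid] = float(np.mean(his))
        out.append(RegionAggregate(region=key, members=idxs,
                                   mean_min=mean_min, mean_max=mean_max))
    return out


def mofva_over_mesh(
    community: CommunityModel,
    mesh: ParetoMesh,
    alpha: float = DEFAULT_ALPHA,
    reactions: list[str] | None = None,
) -> list[FluxRangeSet]:
    """MO-FVA at every mesh point (pure per-point LPs, order-independent)."""
    return [
        mofva_at_point(community, f_star, alpha=alpha, reactions=reactions)
        for _, f_star in mesh.points
    ]
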