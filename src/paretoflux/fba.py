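"""Single-objective flux balance analysis (FBA) and flux variability analysis
(FVA) on any CBM, strain or community.

FBA solves  max c'v  s.t.  Sv = 0, l <= v <= u  (plus community couplings).
FVA then fixes a fraction ``alpha`` of the FBA optimum, c'v >= alpha * z*, and
reports per-reaction flux ranges [vmin, vmax].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import CommunityModel
from .core import StrainModel
from .errors import SolverError, ValidationError
from .lp import compile_lp, objective_vector, solve_max


@dataclass
class FBAResult:
    z_star: float | None
    v: np.ndarray | None
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRangeSet:
    """Per-reaction flux ranges at a fraction ``alpha`` of an optimum.

    ``reference`` is the FBA z* (scalar) or the Pareto point f* (vector) whose
    alpha-fraction was enforced.
    """

    alpha: float
    ranges: dict[str, tuple[float, float]]
    reference: float | np.ndarray

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction\tvmin\tvmax\n")
            for rid, (lo, hi) in self.ranges.items():
                fh.write(f"{rid}\t{lo!r}\t{hi!r}\n")


def fba(model: StrainModel | CommunityModel, objective=None) -> FBAResult:
    """Maximize a linear objective over the flux space.

    Infeasibility and unboundedness are reported in ``status``, never raised.
    """
    lp = compile_lp(model)
    c = objective_vector(model, objective)
    sol = solve_max(c, lp)
    if not sol.optimal:
        return FBAResult(z_star=None, v=None, status=sol.status)
    return FBAResult(z_star=sol.objective, v=sol.x, status="optimal")


def fva(
    model: StrainModel | CommunityModel,
    objective=None,
    alpha: float = 1.0,
    reactions: list[str] | None = None,
) -> FluxRangeSet:
    """Per-reaction flux ranges subject to retaining c'v >= alpha * z*.

    ``reactions`` restricts the sweep to the named reactions (community names
    are ``"strain:rxn"`` / ``"pool:EX_met"``); default is all reactions.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    lp = compile_lp(model)
    c = objective_vector(model, objective)
    base = solve_max(c, lp)
    if not base.optimal:
        raise SolverError(
            f"FVA base FBA is {base.status}", status=base.status
        )
    z_star = base.objective
    if z_star < 0:
        # alpha-scaling a negative optimum flips the inequality's meaning;
        # growth objectives are non-negative, so refuse rather than guess.
        raise ValidationError(
            f"FVA requires a non-negative FBA optimum for alpha-scaling, got {z_star}"
        )
    constrained = lp.with_rows(A_ub=-c, b_ub=-alpha * z_star)
    names = lp.names
    wanted = names if reactions is None else list(reactions)
    idx = {nm: i for i, nm in enumerate(names)}
    ranges: dict[str, tuple[float, float]] = {}
    e = np.zeros(lp.n)
    for rid in wanted:
        j = idx[rid]
        e[:] = 0.0
        e[j] = 1.0
        hi = solve_max(e, constrained)
        lo = solve_max(-e, constrained)
        if not (hi.optimal and lo.optimal):
            raise SolverError(
                f"FVA subproblem for {rid} is {hi.status if not hi.optimal else lo.status}"
            )
        vmin, vmax = -lo.objective, hi.objective
        if vmin > vmax:  # solver jitter on a fixed flux
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rid] = (vmin, vmax)
    return FluxRangeSet(alpha=alpha, ranges=ranges, reference=z_star)
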