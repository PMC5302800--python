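"""Minimal LP solve contract over scipy's HiGHS backend.

All analyses in this package reduce to: maximize c'v subject to equality rows,
inequality rows and box bounds.  This module owns the single place where a
CBM (strain or community) is compiled to that standard form, so GLPK-class or
commercial backends could be swapped in behind :func:`solve_max`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .community import CommunityModel
from .core import StrainModel

#: LP feasibility tolerance (solver default class).
FEAS_TOL = 1e-7
#: Tolerance for comparing flux ranges / objective values.
RANGE_TOL = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class StandardLP:
    """max c'v  s.t.  A_eq v = b_eq,  A_ub v <= b_ub,  lb <= v <= ub."""

    lb: np.ndarray
    ub: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    A_ub: np.ndarray = field(default=None)  # type: ignore[assignment]
    b_ub: np.ndarray = field(default=None)  # type: ignore[assignment]
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.lb)
        if self.A_ub is None:
            self.A_ub = np.zeros((0, n))
            self.b_ub = np.zeros(0)

    @property
    def n(self) -> int:
        return len(self.lb)

    def with_rows(self, A_ub=None, b_ub=None, A_eq=None, b_eq=None) -> "StandardLP":
        """A copy with extra inequality/equality rows appended."""
        new = StandardLP(
            lb=self.lb, ub=self.ub,
            A_eq=self.A_eq if A_eq is None else np.vstack([self.A_eq, np.atleast_2d(A_eq)]),
            b_eq=self.b_eq if b_eq is None else np.concatenate([self.b_eq, np.atleast_1d(b_eq)]),
            A_ub=self.A_ub if A_ub is None else np.vstack([self.A_ub, np.atleast_2d(A_ub)]),
            b_ub=self.b_ub if b_ub is None else np.concatenate([self.b_ub, np.atleast_1d(b_ub)]),
            names=self.names,
        )
        return new


@dataclass
class LPSolution:
    status: str                      # optimal | infeasible | unbounded | ...
    objective: float | None = None
    x: np.ndarray | None = None
    ineq_duals: np.ndarray | None = None
    eq_duals: np.ndarray | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def compile_lp(model: StrainModel | CommunityModel) -> StandardLP:
    """Compile a strain or community CBM to standard form (Sv=0 + couplings)."""
    if isinstance(model, StrainModel):
        S = model.stoichiometric_matrix()
        lb, ub = model.bounds()
        return StandardLP(
            lb=lb, ub=ub,
            A_eq=S, b_eq=np.zeros(S.shape[0]),
            names=list(model.reaction_ids),
        )
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    lp = StandardLP(
        lb=lb, ub=ub,
        A_eq=S, b_eq=np.zeros(S.shape[0]),
        names=list(model.reaction_ids),
    )
    if model.couplings:
        A, rhs, rels = model.coupling_rows()
        eq = [i for i, r in enumerate(rels) if r == "eq"]
        le = [i for i, r in enumerate(rels) if r == "le"]
        ge = [i for i, r in enumerate(rels) if r == "ge"]
        A_ub = np.vstack([A[le], -A[ge]]) if (le or ge) else None
        b_ub = np.concatenate([rhs[le], -rhs[ge]]) if (le or ge) else None
        lp = lp.with_rows(
            A_ub=A_ub, b_ub=b_ub,
            A_eq=A[eq] if eq else None, b_eq=rhs[eq] if eq else None,
        )
    return lp


def objective_vector(model: StrainModel | CommunityModel, objective=None) -> np.ndarray:
    """Resolve an objective argument to a dense vector over model columns.

    ``objective`` may be None (strain: its own objective; community: sum of
    strain objectives), a dense vector, or a mapping from reaction name to
    coefficient (community names are ``"strain:rxn"``).
    """
    if isinstance(model, StrainModel):
        n = len(model.reactions)
        names = model.reaction_ids
        default = model.objective_vector()
    else:
        n = model.n_reactions
        names = model.reaction_ids
        default = model.objective_matrix().sum(axis=1)
    if objective is None:
        return default
    if isinstance(objective, dict):
        idx = {nm: i for i, nm in enumerate(names)}
        c = np.zeros(n)
        for nm, coef in objective.items():
            c[idx[nm]] = coef
        return c
    c = np.asarray(objective, dtype=float)
    if c.shape != (n,):
        raise ValueError(f"objective vector has shape {c.shape}, expected ({n},)")
    return c


def solve_max(c: np.ndarray, lp: StandardLP) -> LPSolution:
    """Maximize c'v over the standard-form polyhedron."""
    res = linprog(
        -np.asarray(c, dtype=float),
        A_ub=lp.A_ub if lp.A_ub.size else None,
        b_ub=lp.b_ub if lp.A_ub.size else None,
        A_eq=lp.A_eq if lp.A_eq.size else None,
        b_eq=lp.b_eq if lp.A_eq.size else None,
        bounds=np.column_stack([lp.lb, lp.ub]),
        method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return LPSolution(status=status)
    ineq_duals = eq_duals = None
    if lp.A_ub.size and res.ineqlin is not None:
        ineq_duals = np.asarray(res.ineqlin.marginals)
    if lp.A_eq.size and res.eqlin is not None:
        eq_duals = np.asarray(res.eqlin.marginals)
    return LPSolution(
        status="optimal",
        objective=-res.fun,
        x=np.asarray(res.x),
        ineq_duals=ineq_duals,
        eq_duals=eq_duals,
    )
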