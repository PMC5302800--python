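"""Community assembly: k strain CBMs + a shared pool compartment.

The community stoichiometric matrix ``S^sigma`` is block-diagonal in the
strain matrices; for every *shared* (pool) metabolite an extra pool row
mirrors each strain's exchange column with sign -1, so that a strain export
deposits the metabolite into the pool, and a pool<->environment exchange
column drains the pool.  Steady state applies to pool rows exactly as to
strain rows.  Linear flux couplings (e.g. a fixed oxygenase/carboxylase
ratio) are stored symbolically and appended as extra LP rows, leaving
``S^sigma`` purely chemical.

Community reaction (column) naming: ``"<strain_id>:<reaction_id>"`` for
strain reactions and ``"pool:EX_<metabolite_id>"`` for pool-environment
exchanges, in that order; the column count is
``n_bar = sum(strain reactions) + len(pool.shared)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DEFAULT_BOUND, StrainModel
from .errors import ValidationError

POOL_ID = "pool"


@dataclass
class PoolSpec:
    """Shared pool metabolites and their environment-exchange bounds.

    ``env_exchange`` maps metabolite id -> (lb, ub) for the pool->environment
    flux (positive = export to the environment, negative = uptake from it).
    Metabolites without an entry default to export-only ``(0, 1000)``: nutrient
    caps are what make community fronts non-trivial, so supplies must be
    requested explicitly.
    """

    shared: list[str] = field(default_factory=list)
    env_exchange: dict[str, tuple[float, float]] = field(default_factory=dict)

    def bounds_for(self, met: str) -> tuple[float, float]:
        return self.env_exchange.get(met, (0.0, DEFAULT_BOUND))


@dataclass
class LinearCoupling:
    """A linear constraint  sum(coef * v[strain, rxn])  <rel>  rhs."""

    terms: list[tuple[str, str, float]]
    rhs: float = 0.0
    relation: str = "eq"  # eq | le | ge

    def validate(self) -> None:
        if self.relation not in ("eq", "le", "ge"):
            raise ValidationError(f"coupling: unknown relation {self.relation!r}")
        if not self.terms:
            raise ValidationError("coupling with no terms")


@dataclass
class CommunityModel:
    strains: list[StrainModel]
    pool: PoolSpec = field(default_factory=PoolSpec)
    couplings: list[LinearCoupling] = field(default_factory=list)

    # -- index space ---------------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.strains)

    @property
    def reaction_ids(self) -> list[str]:
        ids = [f"{s.id}:{r.id}" for s in self.strains for r in s.reactions]
        ids += [f"{POOL_ID}:EX_{m}" for m in self.pool.shared]
        return ids

    @property
    def pool_exchange_ids(self) -> list[str]:
        return [f"{POOL_ID}:EX_{m}" for m in self.pool.shared]

    @property
    def n_reactions(self) -> int:
        return sum(len(s.reactions) for s in self.strains) + len(self.pool.shared)

    def column_index(self, strain_id: str, rxn_id: str) -> int:
        off = 0
        for s in self.strains:
            if s.id == strain_id:
                for j, r in enumerate(s.reactions):
                    if r.id == rxn_id:
                        return off + j
                raise ValidationError(
                    f"strain {strain_id} has no reaction {rxn_id!r}"
                )
            off += len(s.reactions)
        if strain_id == POOL_ID:
            base = sum(len(s.reactions) for s in self.strains)
            for j, m in enumerate(self.pool.shared):
                if f"EX_{m}" == rxn_id:
                    return base + j
            raise ValidationError(f"pool has no exchange {rxn_id!r}")
        raise ValidationError(f"unknown strain {strain_id!r}")

    # -- derived matrices ----------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """S^sigma: strain rows block-diagonally, then one pool row per
        shared metabolite mirroring strain exchange columns with sign -1."""
        n = self.n_reactions
        n_strain_rows = sum(len(s.metabolites) for s in self.strains)
        S = np.zeros((n_strain_rows + len(self.pool.shared), n))
        shared = set(self.pool.shared)
        pool_row = {m: n_strain_rows + i for i, m in enumerate(self.pool.shared)}

        row_off = col_off = 0
        for s in self.strains:
            block = s.stoichiometric_matrix()
            nr, nc = block.shape
            S[row_off:row_off + nr, col_off:col_off + nc] = block
            for j, rxn in enumerate(s.reactions):
                if rxn.kind != "exchange":
                    continue
                for met, coef in rxn.stoich.items():
                    if met in shared:
                        S[pool_row[met], col_off + j] = -coef
            row_off += nr
            col_off += nc
        # pool->environment exchange columns drain the pool
        for i, m in enumerate(self.pool.shared):
            S[pool_row[m], col_off + i] = -1.0
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = [r.lb for s in self.strains for r in s.reactions]
        ub = [r.ub for s in self.strains for r in s.reactions]
        for m in self.pool.shared:
            lo, hi = self.pool.bounds_for(m)
            lb.append(lo)
            ub.append(hi)
        return np.array(lb), np.array(ub)

    def objective_matrix(self) -> np.ndarray:
        """C, shape (n_bar, k): column j is strain j's objective embedded in
        the community index space, zero elsewhere."""
        C = np.zeros((self.n_reactions, self.k))
        off = 0
        for j, s in enumerate(self.strains):
            C[off:off + len(s.reactions), j] = s.objective_vector()
            off += len(s.reactions)
        return C

    def coupling_rows(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Couplings as (A, rhs, relations) over community columns."""
        A = np.zeros((len(self.couplings), self.n_reactions))
        rhs = np.zeros(len(self.couplings))
        rels = []
        for i, c in enumerate(self.couplings):
            for strain_id, rxn_id, coef in c.terms:
                A[i, self.column_index(strain_id, rxn_id)] += coef
            rhs[i] = c.rhs
            rels.append(c.relation)
        return A, rhs, rels

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        if not self.strains:
            raise ValidationError("community with no strains")
        ids = [s.id for s in self.strains]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate strain ids {dup}")
        if POOL_ID in ids:
            raise ValidationError(f"strain id {POOL_ID!r} is reserved")
        for s in self.strains:
            s.validate()
        for m in self.pool.shared:
            exchanged = any(
                m in r.stoich
                for s in self.strains
                for r in s.reactions
                if r.kind == "exchange"
            )
            if not exchanged:
                raise ValidationError(
                    f"pool metabolite {m!r} is exchanged by no strain"
                )
        for c in self.couplings:
            c.validate()
            for strain_id, rxn_id, _ in c.terms:
                self.column_index(strain_id, rxn_id)  # raises if unknown


def assemble_community(
    strains: list[StrainModel],
    pool: PoolSpec | None = None,
    couplings: list[LinearCoupling] | None = None,
) -> CommunityModel:
    """Assemble strain CBMs into a community CBM with a shared pool.

    Every strain exchange of a shared metabolite is routed through the pool
    (its pool row), never directly to the environment; non-shared external
    metabolites keep their direct strain-environment exchange.
    """
    model = CommunityModel(
        strains=list(strains),
        pool=pool if pool is not None else PoolSpec(),
        couplings=list(couplings) if couplings else [],
    )
    model.validate()
    return model


def add_ratio_coupling(
    model: CommunityModel, strain: str, rxn_a: str, rxn_b: str, rho: float
) -> CommunityModel:
    """Constrain  v[strain, rxn_a] = rho * v[strain, rxn_b]  (in place).

    This is how a fixed flux ratio between two reactions of one strain (for
    instance an oxygenase/carboxylase branching ratio) is imposed linearly.
    """
    coupling = LinearCoupling(
        terms=[(strain, rxn_a, 1.0), (strain, rxn_b, -rho)],
        rhs=0.0,
        relation="eq",
    )
    # raises ValidationError for unknown strain/reactions
    for strain_id, rxn_id, _ in coupling.terms:
        model.column_index(strain_id, rxn_id)
    model.couplings.append(coupling)
    return model
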