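"""Core data model: metabolites, reactions, single-strain models, thermodynamic tables.

A strain model is an ordinary constraint-based model (CBM): a stoichiometric
matrix ``S`` (rows = metabolites, columns = reactions, reactants negative,
products positive), flux bounds ``l <= v <= u`` in mmol/gDW/h, and a linear
growth objective ``c``.  Metabolites flagged ``external`` cross the strain
boundary; reactions are partitioned by ``kind`` into internal reactions (the
submatrix over non-exchange columns), exchange reactions, and exactly one
biomass reaction per strain.

Sign convention for exchange fluxes: positive flux exports the metabolite out
of the compartment, negative flux is uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Default flux bound magnitude, mmol/gDW/h (community convention).
DEFAULT_BOUND = 1000.0

REACTION_KINDS = ("internal", "exchange", "biomass")


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    external: bool = False
    mu0: float | None = None          # standard chemical potential, kJ/mol
    conc_lo: float | None = None      # molar concentration bounds
    conc_hi: float | None = None

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("metabolite with empty id")
        if self.conc_lo is not None and self.conc_hi is not None:
            if self.conc_lo > self.conc_hi:
                raise ValidationError(
                    f"metabolite {self.id}: conc_lo > conc_hi"
                )


@dataclass
class Reaction:
    """A reaction as a sparse stoichiometry map plus bounds.

    ``stoich`` maps metabolite id to signed coefficient (reactants negative,
    products positive).
    """

    id: str
    stoich: dict[str, float]
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    kind: str = "internal"

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("reaction with empty id")
        if not self.stoich:
            raise ValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lb > self.ub:
            raise ValidationError(
                f"reaction {self.id}: lb ({self.lb}) > ub ({self.ub})"
            )
        if self.kind not in REACTION_KINDS:
            raise ValidationError(
                f"reaction {self.id}: unknown kind {self.kind!r}"
            )


@dataclass
class StrainModel:
    """One organism's CBM.

    Column order of the implied matrix ``S`` follows ``reactions``; the
    internal/exchange partition is derived from reaction kinds.  ``objective``
    maps reaction id -> coefficient; by construction of :meth:`validate` it has
    at least one nonzero entry and a single biomass reaction exists.
    """

    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)

    # -- structure -----------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def biomass_reaction(self) -> Reaction:
        for r in self.reactions:
            if r.kind == "biomass":
                return r
        raise ValidationError(f"strain {self.id}: no biomass reaction")

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S, rows in metabolite order, columns in reaction order."""
        midx = {m: i for i, m in enumerate(self.metabolite_ids)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoich.items():
                S[midx[met], j] = coef
        return S

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        for j, rid in enumerate(self.reaction_ids):
            c[j] = self.objective.get(rid, 0.0)
        return c

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([r.lb for r in self.reactions]),
                np.array([r.ub for r in self.reactions]))

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("strain with empty id")
        ids = self.metabolite_ids
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"strain {self.id}: duplicate metabolite ids {dup}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ValidationError(f"strain {self.id}: duplicate reaction ids {dup}")
        for m in self.metabolites:
            m.validate()
        known = set(ids)
        external = {m.id for m in self.metabolites if m.external}
        n_biomass = 0
        for r in self.reactions:
            r.validate()
            missing = set(r.stoich) - known
            if missing:
                raise ValidationError(
                    f"strain {self.id}: reaction {r.id} references unknown "
                    f"metabolites {sorted(missing)}"
                )
            if r.kind == "biomass":
                n_biomass += 1
            if r.kind == "exchange" and not (set(r.stoich) & external):
                raise ValidationError(
                    f"strain {self.id}: exchange reaction {r.id} touches no "
                    "external metabolite"
                )
        if n_biomass != 1:
            raise ValidationError(
                f"strain {self.id}: expected exactly one biomass reaction, "
                f"found {n_biomass}"
            )
        bad = set(self.objective) - set(rids)
        if bad:
            raise ValidationError(
                f"strain {self.id}: objective references unknown reactions {sorted(bad)}"
            )
        if not any(v != 0 for v in self.objective.values()):
            raise ValidationError(f"strain {self.id}: objective is all zero")


@dataclass
class ThermoTable:
    """Standard chemical potentials mu0 (kJ/mol) and the concentration-range
    half-width dg = RT ln(x_hi/x0) (kJ/mol) per exchange metabolite.

    dg = 0 marks fixed-concentration species (water, photons).
    """

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)
    temperature: float = 348.15  # kelvin

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("thermo table: non-positive temperature")
        for met, (mu0, dg) in self.entries.items():
            if dg < 0:
                raise ValidationError(f"thermo table: dg < 0 for {met}")

    def mu0(self, met: str) -> float:
        try:
            return self.entries[met][0]
        except KeyError:
            raise ValidationError(f"no standard chemical potential for {met!r}")

    def dg(self, met: str) -> float:
        try:
            return self.entries[met][1]
        except KeyError:
            raise ValidationError(f"no dg entry for {met!r}")
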