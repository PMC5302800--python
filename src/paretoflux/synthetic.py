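"""Synthetic communities with known ground truth.

Three generators cover the pipeline's test surface without any external data:

* :func:`make_competition` -- k strains drawing one pooled nutrient with
  per-strain biomass yields; the Pareto front is known in closed form (the
  simplex ``sum_j f_j / (y_j * cap) <= 1``).
* :func:`make_crossfeed` -- a primary producer fixes an environmental
  substrate into an organic acid that is the consumers' only carbon source,
  mimicking producer/consumer guild structure.
* :func:`random_community` -- seeded random communities that are feasible by
  construction (every strain carries a substrate->biomass chain).

Fluxes are in mmol/gDW/h and yields in h^-1 per mmol/gDW/h throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import CommunityModel, PoolSpec, assemble_community
from .core import DEFAULT_BOUND, Metabolite, Reaction, StrainModel
from .errors import ValidationError
from .mofba import ParetoFront


@dataclass
class ToySpec:
    """Parameters of the closed-form toy communities."""

    n_strains: int = 2
    yields: tuple[float, ...] = (1.0, 0.5)     # biomass per unit nutrient
    nutrient_cap: float = 10.0                 # pooled supply, mmol/gDW/h
    crossfeed: list[tuple[int, int]] | None = None  # producer -> consumer edges
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 1:
            raise ValidationError("need at least one strain")
        if len(self.yields) != self.n_strains:
            raise ValidationError("one yield per strain required")
        if any(y <= 0 for y in self.yields):
            raise ValidationError("yields must be > 0")
        if self.nutrient_cap < 0:
            raise ValidationError("nutrient cap must be >= 0")


def _competition_strain(idx: int, y: float) -> StrainModel:
    sid = f"S{idx + 1}"
    return StrainModel(
        id=sid,
        metabolites=[Metabolite(id="N", name="shared nutrient", external=True)],
        reactions=[
            Reaction(id="EX_N", stoich={"N": -1.0}, lb=-DEFAULT_BOUND, ub=0.0,
                     kind="exchange"),
            Reaction(id="BIOMASS", stoich={"N": -1.0 / y}, lb=0.0,
                     ub=DEFAULT_BOUND, kind="biomass"),
        ],
        objective={"BIOMASS": 1.0},
    )


def make_competition(spec: ToySpec) -> tuple[CommunityModel, ParetoFront]:
    """k strains competing for one pooled nutrient; closed-form front.

    The front is the simplex with one vertex ``y_j * cap`` on each axis and
    the single facet ``sum_j f_j / (y_j * cap) <= 1`` (for cap > 0).
    """
    spec.validate()
    if spec.crossfeed:
        raise ValidationError("competition spec must have no crossfeed edges")
    strains = [_competition_strain(i, y) for i, y in enumerate(spec.yields)]
    pool = PoolSpec(shared=["N"],
                    env_exchange={"N": (-spec.nutrient_cap, DEFAULT_BOUND)})
    model = assemble_community(strains, pool)

    k = spec.n_strains
    cap = spec.nutrient_cap
    if cap == 0:
        front = ParetoFront(
            k=k, vertices=np.zeros((1, k)),
            facets=[(np.eye(k)[j], 0.0) for j in range(k)],
        )
    else:
        verts = np.diag([y * cap for y in spec.yields])
        normal = np.array([1.0 / (y * cap) for y in spec.yields])
        front = ParetoFront(k=k, vertices=verts, facets=[(normal, 1.0)])
        if k == 1:
            front.facets = [(np.array([1.0]), spec.yields[0] * cap)]
    return model, front


def make_crossfeed(spec: ToySpec) -> CommunityModel:
    """Producer/consumer community: strain 1 fixes substrate into an organic
    acid exported to the pool; the other strains grow only on that acid.

    ``spec.crossfeed`` may list (producer, consumer) index edges; only edges
    from strain 0 are supported and the graph must be acyclic.  Consumer
    growth is impossible when the producer is off (its substrate uptake is the
    acid's only source).
    """
    spec.validate()
    if spec.n_strains < 2:
        raise ValidationError("crossfeed community needs >= 2 strains")
    edges = spec.crossfeed
    if edges is None:
        edges = [(0, j) for j in range(1, spec.n_strains)]
    _check_acyclic(edges, spec.n_strains)

    y0 = spec.yields[0]
    producer = StrainModel(
        id="PROD",
        metabolites=[
            Metabolite(id="SUB", name="substrate", external=True),
            Metabolite(id="ACID", name="organic acid", external=True),
        ],
        reactions=[
            Reaction(id="EX_SUB", stoich={"SUB": -1.0}, lb=-spec.nutrient_cap,
                     ub=0.0, kind="exchange"),
            Reaction(id="FIX", stoich={"SUB": -1.0, "ACID": 1.0}, lb=0.0,
                     ub=DEFAULT_BOUND, kind="internal"),
            Reaction(id="EX_ACID", stoich={"ACID": -1.0}, lb=0.0,
                     ub=DEFAULT_BOUND, kind="exchange"),
            Reaction(id="BIOMASS", stoich={"SUB": -1.0 / y0}, lb=0.0,
                     ub=DEFAULT_BOUND, kind="biomass"),
        ],
        objective={"BIOMASS": 1.0},
    )
    consumers = []
    for j in range(1, spec.n_strains):
        yj = spec.yields[j]
        consumers.append(StrainModel(
            id=f"CONS{j}",
            metabolites=[Metabolite(id="ACID", name="organic acid", external=True)],
            reactions=[
                Reaction(id="EX_ACID", stoich={"ACID": -1.0}, lb=-DEFAULT_BOUND,
                         ub=0.0, kind="exchange"),
                Reaction(id="BIOMASS", stoich={"ACID": -1.0 / yj}, lb=0.0,
                         ub=DEFAULT_BOUND, kind="biomass"),
            ],
            objective={"BIOMASS": 1.0},
        ))
    # acid only cycles through the pool; no environmental acid supply
    pool = PoolSpec(shared=["ACID"], env_exchange={"ACID": (0.0, DEFAULT_BOUND)})
    return assemble_community([producer] + consumers, pool)


def _check_acyclic(edges, k):
    adj: dict[int, list[int]] = {i: [] for i in range(k)}
    for a, b in edges:
        if not (0 <= a < k and 0 <= b < k):
            raise ValidationError(f"crossfeed edge ({a}, {b}) out of range")
        adj[a].append(b)
    state = [0] * k

    def visit(u):
        if state[u] == 1:
            raise ValidationError("crossfeed specification is cyclic")
        if state[u] == 2:
            return
        state[u] = 1
        for w in adj[u]:
            visit(w)
        state[u] = 2

    for u in range(k):
        visit(u)


def random_community(
    seed: int, k: int = 3, reactions_per_strain: int = 10
) -> CommunityModel:
    """A seeded random community, feasible and bounded by construction.

    Every strain carries a guaranteed uptake -> conversion -> biomass chain on
    a pooled nutrient (supply capped, so objectives are bounded), plus random
    internal conversions and byproduct exports drawn from the seed.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if reactions_per_strain < 3:
        raise ValidationError("need >= 3 reactions per strain (chain of length 3)")
    rng = np.random.default_rng(seed)
    cap = float(np.round(rng.uniform(5.0, 15.0), 3))
    strains = []
    for i in range(k):
        sid = f"R{i + 1}"
        yield_i = float(np.round(rng.uniform(0.2, 2.0), 3))
        mets = [
            Metabolite(id="NUTR", name="pooled nutrient", external=True),
            Metabolite(id="A", name="intermediate A"),
            Metabolite(id="B", name="intermediate B"),
        ]
        reactions = [
            Reaction(id="EX_NUTR", stoich={"NUTR": -1.0}, lb=-DEFAULT_BOUND,
                     ub=0.0, kind="exchange"),
            Reaction(id="UPT", stoich={"NUTR": -1.0, "A": 1.0}, lb=0.0,
                     ub=DEFAULT_BOUND),
            Reaction(id="CONV", stoich={"A": -1.0, "B": 1.0}, lb=0.0,
                     ub=DEFAULT_BOUND),
            Reaction(id="BIOMASS", stoich={"B": -1.0 / yield_i}, lb=0.0,
                     ub=DEFAULT_BOUND, kind="biomass"),
        ]
        n_extra_mets = max(0, min(reactions_per_strain - 4, 5))
        for m in range(n_extra_mets):
            mets.append(Metabolite(id=f"X{m}", name=f"random intermediate {m}"))
        internal_ids = [m.id for m in mets if not m.external]
        j = 0
        while len(reactions) < reactions_per_strain:
            r = rng.random()
            if r < 0.6 and len(internal_ids) >= 2:
                a, b = rng.choice(internal_ids, size=2, replace=False)
                # product coefficient <= 1 so no conversion cycle creates mass
                coef = float(np.round(rng.uniform(0.3, 1.0), 3))
                reactions.append(Reaction(
                    id=f"RX{j}", stoich={str(a): -1.0, str(b): coef},
                    lb=0.0, ub=DEFAULT_BOUND))
            else:
                src = str(rng.choice(internal_ids))
                wid = f"W{j}"
                if wid not in [m.id for m in mets]:
                    mets.append(Metabolite(id=wid, name="byproduct", external=True))
                reactions.append(Reaction(
                    id=f"EXP{j}", stoich={src: -1.0, wid: 1.0},
                    lb=0.0, ub=DEFAULT_BOUND))
                reactions.append(Reaction(
                    id=f"EX_{wid}", stoich={wid: -1.0}, lb=0.0,
                    ub=DEFAULT_BOUND, kind="exchange"))
            j += 1
        strains.append(StrainModel(
            id=sid, metabolites=mets, reactions=reactions,
            objective={"BIOMASS": 1.0},
        ))
    pool = PoolSpec(shared=["NUTR"], env_exchange={"NUTR": (-cap, DEFAULT_BOUND)})
    return assemble_community(strains, pool)
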