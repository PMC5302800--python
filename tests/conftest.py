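import numpy as np
import pytest
from hypothesis import settings

from paretoflux import (
    Metabolite,
    Reaction,
    StrainModel,
    ToySpec,
    load_hotspring_fixture,
    make_competition,
    solve_mofba,
)

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def chain_strain(sid: str = "CHAIN", cap: float = 10.0) -> StrainModel:
    """Uptake(<=cap) -> A -> B -> biomass; every flux forced at the optimum."""
    return StrainModel(
        id=sid,
        metabolites=[
            Metabolite(id="A", external=True),
            Metabolite(id="B"),
        ],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -cap, 0.0, "exchange"),
            Reaction("CONV", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"B": -1.0}, 0.0, 1000.0, "biomass"),
        ],
        objective={"BIOMASS": 1.0},
    )


def parallel_strain(cap: float = 10.0) -> StrainModel:
    """Two identical pathways from the substrate to biomass (degenerate FBA)."""
    return StrainModel(
        id="PAR",
        metabolites=[Metabolite(id="A", external=True), Metabolite(id="B")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -cap, 0.0, "exchange"),
            Reaction("P1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("P2", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"B": -1.0}, 0.0, 1000.0, "biomass"),
        ],
        objective={"BIOMASS": 1.0},
    )


@pytest.fixture(scope="session")
def toy_competition():
    """2-strain nutrient competition with the closed-form front."""
    return make_competition(ToySpec(n_strains=2, yields=(1.0, 0.5),
                                    nutrient_cap=10.0))


@pytest.fixture(scope="session")
def hotspring():
    return load_hotspring_fixture()


@pytest.fixture(scope="session")
def hotspring_front(hotspring):
    community, _ = hotspring
    return solve_mofba(community)


def vertex_index(front, point, tol=1e-6):
    """Index of the front vertex matching ``point`` within tol; -1 if absent."""
    p = np.asarray(point, dtype=float)
    for i, v in enumerate(front.vertices):
        if np.max(np.abs(v - p)) <= tol:
            return i
    return -1


@pytest.fixture(scope="session")
def hotspring_anchors(hotspring_front):
    """(P1, P2, P3) axis-vertex indices of the hot-spring front."""
    idx = tuple(
        vertex_index(hotspring_front, p)
        for p in ([1, 0, 0], [0, 1, 0], [0, 0, 1])
    )
    assert -1 not in idx
    return idx
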