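"""MO-FBA: exact fronts, scalarization oracles, invariants."""

import numpy as np
import pytest

from paretoflux import (
    InfeasibleError,
    ToySpec,
    UnboundedObjectiveError,
    ValidationError,
    epsilon_constraint,
    fba,
    make_competition,
    random_community,
    solve_mofba,
    verify_front,
    weighted_sum,
)
from paretoflux.core import Metabolite, Reaction, StrainModel
from paretoflux.community import PoolSpec, assemble_community

from conftest import chain_strain, vertex_index


def simplex_grid(k: int, n: int) -> np.ndarray:
    """All weight vectors (i/n, j/n, ...) on the k-simplex."""
    if k == 2:
        t = np.linspace(0.0, 1.0, n + 1)
        return np.column_stack([t, 1.0 - t])
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pts.append((i / n, j / n, (n - i - j) / n))
    return np.array(pts)


def assert_front_matches_grid_oracle(front, model, grid, tol=1e-6):
    """Independent oracle: dense weight-grid scalarization.

    Every scalarization solution must lie on the computed front boundary and
    dominate no vertex; every front vertex must be recovered by some grid
    weight.
    """
    sols = []
    for lam in grid:
        if not np.any(lam > 0):
            continue
        y = weighted_sum(model, lam)
        sols.append(y)
        assert front.contains(y, tol), (lam, y)
        assert front.on_boundary(y, tol), (lam, y)
        for v in front.vertices:
            assert not (np.all(y >= v - tol) and np.any(y > v + tol)), (lam, y, v)
    sols = np.array(sols)
    for v in front.vertices:
        d = np.min(np.max(np.abs(sols - v), axis=1))
        assert d <= 10 * tol, f"vertex {v} not recovered by the weight grid"


def test_closed_form_competition_front(toy_competition):
    model, closed = toy_competition
    front = solve_mofba(model)
    assert vertex_index(front, [10.0, 0.0]) >= 0
    assert vertex_index(front, [0.0, 5.0]) >= 0
    assert len(front.vertices) == 2
    assert len(front.facets) == 1
    normal, offset = front.facets[0]
    np.testing.assert_allclose(normal / offset, closed.facets[0][0], atol=1e-9)


def test_single_objective_front_degenerates_to_fba():
    s = chain_strain()
    cm = assemble_community([s], PoolSpec())
    front = solve_mofba(cm)
    assert front.k == 1
    assert front.vertices.shape == (1, 1)
    assert front.vertices[0, 0] == pytest.approx(fba(s).z_star)


def test_hotspring_front_has_five_vertices(hotspring_front):
    assert len(hotspring_front.vertices) == 5
    for p in ([1, 0, 0], [0, 1, 0], [0, 0, 1], [0.27, 0.0, 0.89],
              [0.0, 0.46, 0.65]):
        assert vertex_index(hotspring_front, p) >= 0, p


def test_no_vertex_dominates_another(hotspring_front):
    v = hotspring_front.vertices
    for a in v:
        for b in v:
            assert not (np.all(b >= a - 1e-9) and np.any(b > a + 1e-6))


def test_every_vertex_attained_by_a_feasible_flux_vector(hotspring, hotspring_front):
    community, _ = hotspring
    S = community.stoichiometric_matrix()
    C = community.objective_matrix()
    lb, ub = community.bounds()
    for v, x in zip(hotspring_front.vertices, hotspring_front.efficient_points):
        assert np.max(np.abs(S @ x)) < 1e-6
        assert np.all(x >= lb - 1e-7) and np.all(x <= ub + 1e-7)
        np.testing.assert_allclose(C.T @ x, v, atol=1e-6)


class TestWeightedSum:
    def test_unit_weight_reduces_to_single_objective_fba(self, hotspring):
        community, _ = hotspring
        for j, strain in enumerate(community.strains):
            lam = np.eye(3)[j]
            y = weighted_sum(community, lam)
            assert y[j] == pytest.approx(1.0, abs=1e-6)

    def test_equal_weights_pick_the_high_yield_strain(self, toy_competition):
        model, _ = toy_competition
        y = weighted_sum(model, [1.0, 1.0])
        np.testing.assert_allclose(y, [10.0, 0.0], atol=1e-6)

    def test_solution_supports_a_facet(self, hotspring, hotspring_front):
        community, _ = hotspring
        rng = np.random.default_rng(42)
        for _ in range(5):
            lam = rng.dirichlet(np.ones(3)) + 1e-3
            y = weighted_sum(community, lam)
            assert hotspring_front.on_boundary(y, 1e-6)

    def test_invalid_weights_are_rejected(self, toy_competition):
        model, _ = toy_competition
        with pytest.raises(ValidationError):
            weighted_sum(model, [0.0, 0.0])
        with pytest.raises(ValidationError):
            weighted_sum(model, [-1.0, 2.0])


class TestEpsilonConstraint:
    def test_floors_route_all_nutrient_to_strain_one(self, toy_competition):
        model, _ = toy_competition
        y = epsilon_constraint(model, 1, [10.0, 0.0])
        np.testing.assert_allclose(y, [10.0, 0.0], atol=1e-6)

    def test_zero_floors_recover_solo_community_optimum(self, hotspring):
        community, _ = hotspring
        y = epsilon_constraint(community, 0, [0.0, 0.0, 0.0])
        assert y[0] == pytest.approx(1.0, abs=1e-6)

    def test_hotspring_syn_under_srb_floor(self, hotspring):
        community, _ = hotspring
        y = epsilon_constraint(community, 0, [0.0, 0.0, 0.89])
        assert y[0] == pytest.approx(0.27, abs=1e-6)

    def test_infeasible_floors_raise_status_error(self, toy_competition):
        model, _ = toy_competition
        with pytest.raises(InfeasibleError):
            epsilon_constraint(model, 1, [11.0, 0.0])


class TestVerifyFront:
    def test_convexity_property_holds_on_toy(self, toy_competition):
        model, _ = toy_competition
        front = solve_mofba(model)
        assert verify_front(front, model, n_samples=100, seed=3).ok

    def test_sabotaged_front_is_flagged(self, toy_competition):
        import dataclasses

        model, _ = toy_competition
        front = solve_mofba(model)
        # (9.5, 0) is strictly dominated by the true vertex (10, 0)
        bad = dataclasses.replace(
            front,
            vertices=np.vstack([front.vertices, [9.5, 0.0]]),
        )
        report = verify_front(bad, model, n_samples=50, seed=3)
        assert not report.ok

    def test_single_objective_front_trivially_verifies(self):
        cm = assemble_community([chain_strain()], PoolSpec())
        front = solve_mofba(cm)
        assert verify_front(front, cm, n_samples=10, seed=0).ok


def test_scale_covariance_of_vertices(toy_competition):
    model, _ = toy_competition
    import copy

    scaled = copy.deepcopy(model)
    scaled.strains[0].objective["BIOMASS"] = 3.0
    front = solve_mofba(scaled)
    assert vertex_index(front, [30.0, 0.0]) >= 0
    assert vertex_index(front, [0.0, 5.0]) >= 0


def test_unbounded_objective_names_the_strain():
    s = chain_strain("LOOSE")
    s.reaction("EX_A").lb = -np.inf
    s.reaction("CONV").ub = np.inf
    s.reaction("BIOMASS").ub = np.inf
    cm = assemble_community([s, chain_strain("OK")], PoolSpec())
    with pytest.raises(UnboundedObjectiveError, match="LOOSE"):
        solve_mofba(cm)


def test_infeasible_community_raises():
    s = chain_strain()
    s.reaction("BIOMASS").lb = 5.0
    s.reaction("EX_A").lb = 0.0
    cm = assemble_community([s], PoolSpec())
    with pytest.raises(InfeasibleError):
        solve_mofba(cm)


@pytest.mark.parametrize("spec", [
    ToySpec(n_strains=2, yields=(2.0, 0.4), nutrient_cap=3.0),
    ToySpec(n_strains=3, yields=(1.0, 0.5, 0.25), nutrient_cap=8.0),
])
def test_front_matches_closed_form_and_grid_oracle(spec):
    model, closed = make_competition(spec)
    front = solve_mofba(model)
    assert len(front.vertices) == spec.n_strains
    for v in closed.vertices:
        assert vertex_index(front, v) >= 0
    grid = simplex_grid(spec.n_strains, 12)
    assert_front_matches_grid_oracle(front, model, grid)


@pytest.mark.parametrize("seed", [1, 2])
def test_random_community_front_agrees_with_grid_oracle(seed):
    model = random_community(seed, k=3, reactions_per_strain=12)
    front = solve_mofba(model)
    assert len(front.vertices) >= 1
    grid = simplex_grid(3, 8)
    assert_front_matches_grid_oracle(front, model, grid)
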