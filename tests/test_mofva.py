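"""MO-FVA: vector fraction-of-optimum floors, meshing, regional aggregation."""

import numpy as np
import pytest

from paretoflux import (
    InfeasibleError,
    ValidationError,
    aggregate_regions,
    assign_regions,
    fva,
    mesh_front,
    mofva_at_point,
    mofva_over_mesh,
    solve_mofba,
)

from conftest import vertex_index


class TestAtPoint:
    def test_biomass_ranges_collapse_at_a_front_vertex(self, hotspring,
                                                       hotspring_front):
        community, _ = hotspring
        i = vertex_index(hotspring_front, [0.27, 0.0, 0.89])
        f_star = hotspring_front.vertices[i]
        biomass = [f"{s.id}:{s.biomass_reaction.id}" for s in community.strains]
        ranges = mofva_at_point(community, f_star, alpha=1.0, reactions=biomass)
        for rid, fj in zip(biomass, f_star):
            lo, hi = ranges[rid]
            assert lo == pytest.approx(fj, abs=1e-6)
            assert hi == pytest.approx(fj, abs=1e-6)

    def test_zero_component_floor_is_vacuous(self, hotspring):
        community, _ = hotspring
        rid = "FAP:BIOMASS_FAP"
        at_zero = mofva_at_point(community, [0.27, 0.0, 0.89], alpha=0.9,
                                 reactions=[rid])
        lo, hi = at_zero[rid]
        assert lo == pytest.approx(0.0, abs=1e-6)  # the alpha*0 floor is vacuous
        assert hi > 1e-3  # slack from the 90% floors lets FAP grow a little

    def test_alpha_zero_equals_plain_community_fva(self, hotspring):
        community, _ = hotspring
        plain = fva(community, alpha=0.0)
        via_point = mofva_at_point(community, [1.0, 1.0, 1.0], alpha=0.0)
        for rid, (lo, hi) in plain.ranges.items():
            plo, phi = via_point[rid]
            assert lo == pytest.approx(plo, abs=1e-6)
            assert hi == pytest.approx(phi, abs=1e-6)

    def test_ranges_nest_in_alpha(self, hotspring):
        community, _ = hotspring
        f_star = np.array([0.27, 0.0, 0.89])
        wide = mofva_at_point(community, f_star, alpha=0.5)
        narrow = mofva_at_point(community, f_star, alpha=0.95)
        for rid, (lo, hi) in narrow.ranges.items():
            wlo, whi = wide[rid]
            assert lo >= wlo - 1e-6
            assert hi <= whi + 1e-6

    def test_point_above_front_is_infeasible(self, hotspring):
        community, _ = hotspring
        with pytest.raises(InfeasibleError):
            mofva_at_point(community, [1.0, 1.0, 1.0], alpha=1.0)

    def test_every_bound_is_attained_by_a_feasible_flux(self, hotspring):
        """Spot-check attainability: re-solve with the bound pinned."""
        community, _ = hotspring
        f_star = np.array([0.27, 0.0, 0.89])
        ids = ["SYN:EX_NH3", "pool:EX_Ac", "SRB:BIOMASS_SRB"]
        ranges = mofva_at_point(community, f_star, alpha=0.9, reactions=ids)
        from paretoflux.lp import compile_lp, solve_max

        lp = compile_lp(community)
        C = community.objective_matrix()
        lp = lp.with_rows(A_ub=-C.T, b_ub=-0.9 * f_star)
        names = lp.names
        for rid in ids:
            j = names.index(rid)
            for bound in ranges[rid]:
                pinned = lp.with_rows(
                    A_eq=np.eye(lp.n)[j], b_eq=bound)
                assert solve_max(np.zeros(lp.n), pinned).optimal

    def test_pool_mass_balance_of_exchange_ranges(self, hotspring):
        """No pool creation: summed strain NH3 export capacity covers every
        attainable environment-export flux."""
        community, _ = hotspring
        f_star = np.array([0.27, 0.0, 0.89])
        ids = ["SYN:EX_NH3", "FAP:EX_NH3", "SRB:EX_NH3", "pool:EX_NH3"]
        r = mofva_at_point(community, f_star, alpha=0.9, reactions=ids)
        strain_max = sum(r[i][1] for i in ids[:3])
        assert r["pool:EX_NH3"][1] <= strain_max + 1e-6


class TestMesh:
    def test_one_subdivision_returns_the_anchors(self, hotspring_front,
                                                 hotspring_anchors):
        mesh = mesh_front(hotspring_front, hotspring_anchors, n=1)
        assert len(mesh) == 3
        pts = np.array([p for _, p in mesh.points])
        for i in hotspring_anchors:
            v = hotspring_front.vertices[i]
            assert np.min(np.max(np.abs(pts - v), axis=1)) < 1e-12

    @pytest.mark.parametrize("n,count", [(2, 6), (10, 66), (100, 5151)])
    def test_lattice_size_is_triangular_number(self, hotspring_front,
                                               hotspring_anchors, n, count):
        mesh = mesh_front(hotspring_front, hotspring_anchors, n=n)
        assert len(mesh) == count == (n + 1) * (n + 2) // 2

    def test_barycentric_weights_are_convex(self, hotspring_front,
                                            hotspring_anchors):
        mesh = mesh_front(hotspring_front, hotspring_anchors, n=7)
        for w, p in mesh.points:
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(p, w @ mesh.anchors, atol=1e-12)

    def test_epsilon_lift_lands_on_the_front(self, hotspring, hotspring_front,
                                             hotspring_anchors):
        community, _ = hotspring
        mesh = mesh_front(hotspring_front, hotspring_anchors, n=3,
                          community=community, lift="epsilon")
        for _, p in mesh.points:
            assert hotspring_front.on_boundary(p, 1e-6)

    def test_non_three_objective_meshing_is_rejected(self, toy_competition):
        model, _ = toy_competition
        front = solve_mofba(model)
        with pytest.raises(ValidationError, match="3 objectives"):
            mesh_front(front, (0, 1), n=2)  # type: ignore[arg-type]


class TestRegions:
    def test_single_region_aggregates_global_means(self, hotspring,
                                                   hotspring_front,
                                                   hotspring_anchors):
        community, _ = hotspring
        mesh = mesh_front(hotspring_front, hotspring_anchors, n=2)
        ids = ["pool:EX_NH3", "pool:EX_Ac"]
        results = mofva_over_mesh(community, mesh, alpha=0.9, reactions=ids)
        aggs = aggregate_regions(mesh, results, r=1)
        assert len(aggs) == 1
        for rid in ids:
            assert aggs[0].mean_max[rid] == pytest.approx(
                np.mean([r[rid][1] for r in results]))
            assert aggs[0].mean_min[rid] == pytest.approx(
                np.mean([r[rid][0] for r in results]))

    @pytest.mark.parametrize("n,r", [(10, 5), (100, 15)])
    def test_region_count_is_r_squared(self, hotspring_front,
                                       hotspring_anchors, n, r):
        mesh = mesh_front(hotspring_front, hotspring_anchors, n=n)
        keys = assign_regions(mesh, r)
        assert len(keys) == len(mesh)
        assert len(set(keys)) == r * r

    def test_constant_ranges_aggregate_to_the_constant(self, hotspring_front,
                                                       hotspring_anchors):
        from paretoflux import FluxRangeSet

        mesh = mesh_front(hotspring_front, hotspring_anchors, n=4)
        results = [
            FluxRangeSet(alpha=0.9, ranges={"X": (-2.5, 7.0)}, reference=p)
            for _, p in mesh.points
        ]
        for agg in aggregate_regions(mesh, results, r=2):
            assert agg.mean_min["X"] == pytest.approx(-2.5)
            assert agg.mean_max["X"] == pytest.approx(7.0)

    def test_incompatible_resolution_is_rejected(self, hotspring_front,
                                                 hotspring_anchors):
        from paretoflux import FluxRangeSet

        mesh = mesh_front(hotspring_front, hotspring_anchors, n=2)
        results = [FluxRangeSet(alpha=0.9, ranges={"X": (0.0, 1.0)},
                                reference=p) for _, p in mesh.points]
        with pytest.raises(ValidationError, match="empty"):
            aggregate_regions(mesh, results, r=10)
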