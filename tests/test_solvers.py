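"""Exact solvers, enumeration oracle, frontier sweeps and dominance filtering."""

import numpy as np
import pytest

from careassign import (
    Assignment,
    BoundSet,
    CapacityError,
    HelperType,
    Instance,
    ObjectiveVector,
    ScenarioProfile,
    SolveStatus,
    ValidationError,
    WeightVector,
    brute_force_solve,
    composite_weights,
    dominates,
    epsilon_constraint_solve,
    evaluate_objectives,
    full_frontier,
    generate_instance,
    pareto_filter,
    simplex_grid,
    solve_scalarized,
    weight_sweep,
)
from conftest import make_random_instance


def quadratic_pareto_oracle(points):
    """Independent O(n^2) non-dominated filter used as the reference."""
    unique = []
    for p in points:
        if p.as_tuple() not in {q.as_tuple() for q in unique}:
            unique.append(p)
    kept = []
    for p in unique:
        dominated = False
        for q in unique:
            better_somewhere = (
                q.f_efficiency > p.f_efficiency
                or q.f_utilization > p.f_utilization
                or q.f_stress < p.f_stress
            )
            at_least_as_good = (
                q.f_efficiency >= p.f_efficiency
                and q.f_utilization >= p.f_utilization
                and q.f_stress <= p.f_stress
            )
            if at_least_as_good and better_somewhere:
                dominated = True
                break
        if not dominated:
            kept.append(p)
    return kept


class TestCompositeWeights:
    def test_pure_efficiency_weights_project_c(self, two_by_three_instance):
        w = composite_weights(two_by_three_instance, WeightVector(1, 0, 0))
        assert np.array_equal(w, two_by_three_instance.efficiency)

    def test_pure_stress_weights_negate_b(self, two_by_three_instance):
        w = composite_weights(two_by_three_instance, WeightVector(0, 0, 1))
        assert np.array_equal(w, -two_by_three_instance.stress)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(3)
        inst = make_random_instance(rng, 3, 3)
        wv = WeightVector(0.2, 0.3, 0.5)
        w = composite_weights(inst, wv)
        for i in range(3):
            for j in range(3):
                expected = (
                    0.2 * inst.efficiency[i, j]
                    + 0.3 * inst.utilization[i, j]
                    - 0.5 * inst.stress[i, j]
                )
                assert w[i, j] == pytest.approx(expected, abs=1e-12)

    def test_assignment_score_is_sum_of_pair_weights(self):
        rng = np.random.default_rng(4)
        inst = make_random_instance(rng, 4, 5)
        wv = WeightVector(0.4, 0.25, 0.35)
        w = composite_weights(inst, wv)
        pairs = ((inst.elderly_ids[0], inst.helper_ids[2]),
                 (inst.elderly_ids[3], inst.helper_ids[4]))
        score = (
            wv.lambda1 * evaluate_objectives(inst, Assignment(pairs)).f_efficiency
            + wv.lambda2 * evaluate_objectives(inst, Assignment(pairs)).f_utilization
            - wv.lambda3 * evaluate_objectives(inst, Assignment(pairs)).f_stress
        )
        assert score == pytest.approx(w[0, 2] + w[3, 4], abs=1e-12)


class TestSolveScalarized:
    def test_pure_efficiency_picks_caregiver(self, one_elderly_two_helpers):
        res = solve_scalarized(one_elderly_two_helpers, WeightVector(1, 0, 0))
        assert res.assignment.pairs == (("e1", "cg"),)
        assert res.score == pytest.approx(0.9)

    def test_pure_utilization_picks_robot(self, one_elderly_two_helpers):
        res = solve_scalarized(one_elderly_two_helpers, WeightVector(0, 1, 0))
        assert res.assignment.pairs == (("e1", "rb"),)
        assert res.score == pytest.approx(0.8)

    def test_pure_stress_serves_with_robot_at_zero_score(
        self, one_elderly_two_helpers
    ):
        # Serving is preferred over skipping (coverage tie-break); the robot
        # beats the caregiver because 0 > -0.2.
        res = solve_scalarized(one_elderly_two_helpers, WeightVector(0, 0, 1))
        assert res.assignment.pairs == (("e1", "rb"),)
        assert res.score == pytest.approx(0.0, abs=1e-12)

    def test_empty_instance_gives_empty_optimal(self):
        inst = Instance((), (), (), np.zeros((0, 0)), np.zeros((0, 0)), np.zeros((0, 0)))
        res = solve_scalarized(inst, WeightVector(1, 0, 0))
        assert res.status is SolveStatus.OPTIMAL
        assert res.assignment.n_pairs == 0
        assert res.score == 0.0

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            inst = make_random_instance(rng, 4, 6)
            lam = rng.dirichlet([1.0, 1.0, 1.0])
            weights = WeightVector(*(lam / lam.sum()))
            fast = solve_scalarized(inst, weights)
            oracle = brute_force_solve(inst, weights)
            assert fast.score == oracle.score
            assert fast.assignment.pairs == oracle.assignment.pairs

    def test_reference_profile_pure_efficiency_uses_only_caregivers(self):
        inst = generate_instance(ScenarioProfile(seed=9))
        res = solve_scalarized(inst, WeightVector(1, 0, 0))
        assert res.assignment.n_pairs == inst.n_elderly
        for _, helper in res.assignment.pairs:
            j = inst.helper_index[helper]
            assert inst.helper_types[j] is HelperType.CAREGIVER

    def test_full_coverage_when_all_pair_weights_positive(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            inst = make_random_instance(rng, 4, 6)
            # all composite weights positive under pure efficiency weights
            w = composite_weights(inst, WeightVector(1, 0, 0))
            if not np.all(w > 0):
                continue
            res = solve_scalarized(inst, WeightVector(1, 0, 0))
            assert res.assignment.n_pairs == inst.n_elderly

    def test_monotone_stress_along_weight_path(self):
        rng = np.random.default_rng(15)
        inst = make_random_instance(rng, 6, 8)
        stresses = []
        for t in np.linspace(0.0, 1.0, 11):
            weights = WeightVector((1 - t) / 2, (1 - t) / 2, t)
            res = solve_scalarized(inst, weights)
            stresses.append(res.objectives.f_stress)
        for earlier, later in zip(stresses, stresses[1:]):
            assert later <= earlier + 1e-9

    def test_scale_invariance(self):
        rng = np.random.default_rng(16)
        inst = make_random_instance(rng, 5, 7)
        scale = 0.5
        scaled = Instance(
            inst.elderly_ids,
            inst.helper_ids,
            inst.helper_types,
            inst.efficiency * scale,
            inst.utilization * scale,
            inst.stress * scale,
        )
        weights = WeightVector(0.3, 0.3, 0.4)
        base = solve_scalarized(inst, weights)
        after = solve_scalarized(scaled, weights)
        assert after.assignment.pairs == base.assignment.pairs
        assert after.score == pytest.approx(scale * base.score, rel=1e-12)


class TestBruteForce:
    def test_empty_instance(self):
        inst = Instance((), (), (), np.zeros((0, 0)), np.zeros((0, 0)), np.zeros((0, 0)))
        res = brute_force_solve(inst, WeightVector(1, 0, 0))
        assert res.assignment.n_pairs == 0 and res.score == 0.0

    def test_single_pair_instance(self):
        inst = Instance(
            ("e1",), ("h1",), (HelperType.CAREGIVER,), [[0.5]], [[0.0]], [[0.0]]
        )
        res = brute_force_solve(inst, WeightVector(1, 0, 0))
        assert res.assignment.pairs == (("e1", "h1"),)
        assert res.score == pytest.approx(0.5)

    def test_cross_matching_beats_diagonal(self):
        # Composite weights equal efficiency: [[0.9, 0.7], [0.8, 0.1]].
        # The cross matching 0.7 + 0.8 = 1.5 beats the diagonal 0.9 + 0.1.
        inst = Instance(
            ("e1", "e2"),
            ("h1", "h2"),
            (HelperType.CAREGIVER, HelperType.CAREGIVER),
            [[0.9, 0.7], [0.8, 0.1]],
            np.zeros((2, 2)),
            np.zeros((2, 2)),
        )
        res = brute_force_solve(inst, WeightVector(1, 0, 0))
        assert res.assignment.pairs == (("e1", "h2"), ("e2", "h1"))
        assert res.score == pytest.approx(1.5)

    def test_size_guard(self):
        rng = np.random.default_rng(0)
        inst = make_random_instance(rng, 7, 8)
        with pytest.raises(CapacityError, match="limited"):
            brute_force_solve(inst, WeightVector(1, 0, 0))


class TestWeightSweep:
    def test_resolution_two_grid_is_the_six_reference_vectors(self):
        grid = {wv.as_tuple() for wv in simplex_grid(2)}
        assert grid == {
            (1.0, 0.0, 0.0),
            (0.0, 1.0, 0.0),
            (0.0, 0.0, 1.0),
            (0.5, 0.5, 0.0),
            (0.5, 0.0, 0.5),
            (0.0, 0.5, 0.5),
        }

    def test_zero_resolution_rejected(self):
        with pytest.raises(ValidationError):
            simplex_grid(0)

    def test_single_caregiver_instance_collapses(self):
        inst = Instance(
            ("e1",), ("h1",), (HelperType.CAREGIVER,), [[0.5]], [[0.0]], [[0.0]]
        )
        points = weight_sweep(inst, 4)
        assert len(points) <= 2
        assert all(p.supported for p in points)

    def test_sweep_points_contained_in_full_frontier(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            inst = make_random_instance(rng, 4, 6)
            frontier_objs = [p.objectives for p in full_frontier(inst)]
            for point in weight_sweep(inst, 10):
                assert any(
                    np.allclose(
                        point.objectives.as_tuple(), fo.as_tuple(), atol=1e-9
                    )
                    for fo in frontier_objs
                )


class TestEpsilonConstraint:
    def test_unbounded_matches_weighted_sum_optimum(self):
        rng = np.random.default_rng(31)
        inst = make_random_instance(rng, 4, 5)
        eps = epsilon_constraint_solve(inst, 1, BoundSet())
        weighted = solve_scalarized(inst, WeightVector(1, 0, 0))
        assert eps.status is SolveStatus.OPTIMAL
        assert eps.objectives.f_efficiency == pytest.approx(
            weighted.objectives.f_efficiency, abs=1e-9
        )

    def test_zero_stress_bound_forces_robot_only_assignments(self):
        rng = np.random.default_rng(32)
        inst = make_random_instance(rng, 3, 4)
        # ensure all caregivers carry positive stress
        if not np.all(inst.stress[:, ~inst.robot_mask] > 0):
            pytest.skip("fixture draw produced a zero-stress caregiver")
        eps = epsilon_constraint_solve(inst, 1, BoundSet(max_stress=0.0))
        assert eps.status is SolveStatus.OPTIMAL
        for _, helper in eps.assignment.pairs:
            assert inst.robot_mask[inst.helper_index[helper]]
        # independent oracle: best robot-only matching on efficiency,
        # enumerated directly
        robots = [j for j in range(inst.n_helpers) if inst.robot_mask[j]]
        best = 0.0
        import itertools

        for k in range(min(3, len(robots)) + 1):
            for rows in itertools.permutations(range(3), k):
                for cols in itertools.permutations(robots, k):
                    best = max(
                        best,
                        sum(inst.efficiency[i, j] for i, j in zip(rows, cols)),
                    )
        assert eps.objectives.f_efficiency == pytest.approx(best, abs=1e-9)

    def test_unreachable_efficiency_bound_is_infeasible(self):
        rng = np.random.default_rng(33)
        inst = make_random_instance(rng, 3, 4)
        eps = epsilon_constraint_solve(
            inst, 2, BoundSet(min_efficiency=inst.n_elderly + 1.0)
        )
        assert eps.status is SolveStatus.INFEASIBLE
        assert eps.assignment is None

    def test_size_guard(self):
        rng = np.random.default_rng(34)
        inst = make_random_instance(rng, 11, 12)
        with pytest.raises(CapacityError):
            epsilon_constraint_solve(inst, 1)


class TestFullFrontier:
    def test_single_caregiver_keeps_serve_and_skip(self):
        inst = Instance(
            ("e1",), ("h1",), (HelperType.CAREGIVER,), [[0.5]], [[0.0]], [[0.4]]
        )
        points = full_frontier(inst)
        objs = sorted(p.objectives.as_tuple() for p in points)
        assert objs == [(0.0, 0.0, 0.0), (0.5, 0.0, 0.4)]

    def test_points_pairwise_non_dominated(self):
        rng = np.random.default_rng(51)
        for _ in range(5):
            inst = make_random_instance(rng, 3, 4)
            points = full_frontier(inst)
            for p in points:
                for q in points:
                    assert not dominates(p.objectives, q.objectives) or p is q

    def test_size_guard(self):
        rng = np.random.default_rng(52)
        inst = make_random_instance(rng, 7, 8)
        with pytest.raises(CapacityError):
            full_frontier(inst)


class TestParetoFilter:
    def test_singleton(self):
        p = ObjectiveVector(1.0, 2.0, 3.0)
        assert pareto_filter([p]) == [p]

    def test_direct_domination(self):
        strong = ObjectiveVector(1, 1, 0)
        weak = ObjectiveVector(0.5, 0.5, 0.5)
        assert pareto_filter([weak, strong]) == [strong]

    def test_matches_quadratic_oracle_on_random_vectors(self):
        rng = np.random.default_rng(61)
        points = [
            ObjectiveVector(*rng.random(3).round(2)) for _ in range(100)
        ]
        assert pareto_filter(points) == quadratic_pareto_oracle(points)
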