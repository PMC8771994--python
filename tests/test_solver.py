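"""Solver behavior: indices, greedy construction, branch-and-bound, checking."""

import dataclasses

import pytest

from coldroute import (
    InfeasibleInstanceError,
    Normalizers,
    ObjectiveWeights,
    PartialSolution,
    Vehicle,
    apply_emergency,
    check_feasible,
    cyclone_scenario,
    example_instance,
    facility_index,
    greedy_construct,
    leg_metrics,
    solve,
    vehicle_index,
    visit_set,
)
from coldroute.scenarios import GeneratorSpec, generate_instance
from coldroute.solver import Route, SolverConfig
from coldroute.objective import RouteMetrics, route_metrics
from coldroute import AggregatedLoad
from conftest import make_instance

FAST = SolverConfig(time_budget_seconds=10, branching_width=3)
EXACT = SolverConfig(time_budget_seconds=60, branching_width="all")


class TestIndices:
    def test_facility_index_matches_leg_metrics_recomputation(self, province):
        state = PartialSolution.initial(province)
        state.open_route(0)
        weights = ObjectiveWeights(7)
        norms = Normalizers(5.0, 300.0)
        vehicle = state.compiled.vehicles[0]
        depot = province.parameters.depot_name
        svc = province.parameters.service_hours_per_stop
        for cand in sorted(visit_set(province)):
            got = facility_index(state, cand, weights, norms)
            lm = leg_metrics(depot, cand, vehicle, province.network)
            expected = weights.weight_time * (lm.hours + svc) / norms.time_norm \
                + weights.weight_risk * lm.risk / norms.risk_norm
            assert got == pytest.approx(expected)

    def test_pure_time_weights_order_by_travel_time(self, province):
        state = PartialSolution.initial(province)
        state.open_route(0)
        weights, norms = ObjectiveWeights(10), Normalizers(3.0, 7.0)
        vehicle = state.compiled.vehicles[0]
        depot = province.parameters.depot_name
        cands = sorted(visit_set(province))
        scores = [facility_index(state, c, weights, norms) for c in cands]
        times = [leg_metrics(depot, c, vehicle, province.network).hours
                 for c in cands]
        assert sorted(range(len(cands)), key=scores.__getitem__) == \
            sorted(range(len(cands)), key=times.__getitem__)

    def test_over_capacity_candidate_is_infeasible(self):
        inst = make_instance(cold_demand={"A": 1000},
                             vehicles=[Vehicle("T", True, "Good", 50, 50, 0.2, 2),
                                       Vehicle("U", True, "Good", 5000, 5000, 0.2, 2)])
        state = PartialSolution.initial(inst)
        state.open_route(0)  # "T", 50 L cold
        assert facility_index(state, "A", ObjectiveWeights(5), Normalizers()) is None

    def test_vehicle_with_fewer_routes_ranks_first(self, tiny):
        state = PartialSolution.initial(tiny)
        state.counts = [1]
        busy = tiny.vehicles[0]
        state2 = PartialSolution.initial(tiny)
        assert vehicle_index(state2, busy) < vehicle_index(state, busy)

    def test_identical_vehicles_tie_break_on_name(self):
        v1 = Vehicle("Alpha", True, "Good", 100, 100, 0.2, 2)
        v2 = Vehicle("Beta", True, "Good", 100, 100, 0.2, 2)
        inst = make_instance(vehicles=[v1, v2])
        state = PartialSolution.initial(inst)
        assert vehicle_index(state, v1) < vehicle_index(state, v2)


class TestGreedy:
    def test_single_facility_single_vehicle(self):
        inst = make_instance(("Depot", "F"))
        sol = greedy_construct(inst)
        assert len(sol.routes) == 1
        assert sol.routes[0].stops == ("F",)
        assert check_feasible(sol, inst) == []

    def test_unservable_demand_is_infeasible(self):
        inst = make_instance(cold_demand={"A": 10_000},
                             vehicles=[Vehicle("T", True, "Good", 50, 500, 0.2, 2)])
        with pytest.raises(InfeasibleInstanceError):
            greedy_construct(inst)

    def test_round_trip_exceeding_window_is_infeasible(self):
        inst = make_instance(distances={("Depot", "A"): 900.0}, ret="12:00")
        with pytest.raises(InfeasibleInstanceError):
            greedy_construct(inst)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_instances_give_feasible_solutions(self, seed):
        inst = generate_instance(GeneratorSpec(seed=seed, n_facilities=5,
                                               n_vehicles=2))
        sol = greedy_construct(inst)
        assert check_feasible(sol, inst) == []

    def test_empty_visit_set_gives_empty_solution(self):
        inst = make_instance(cold_demand={"A": 0, "B": 0},
                             demand={"A": 0, "B": 0})
        sol = solve(inst, FAST)
        assert sol.routes == [] and sol.objective_score == 0.0


class TestEvenness:
    def test_three_routes_two_vehicles_split_two_one(self):
        # each facility's cold demand fills a whole vehicle -> 3 routes
        vehicles = [Vehicle("Big", True, "Good", 100, 1000, 0.2, 2),
                    Vehicle("Small", True, "Fair", 90, 1000, 0.2, 2)]
        inst = make_instance(("Depot", "A", "B", "C"),
                             cold_demand={"A": 45, "B": 45, "C": 45},
                             vehicles=vehicles)
        sol = solve(inst, EXACT)
        counts = {}
        for r in sol.routes:
            counts[r.vehicle] = counts.get(r.vehicle, 0) + 1
        assert sorted(counts.values(), reverse=True) == [2, 1]
        assert check_feasible(sol, inst) == []

    def test_days_are_consecutive_per_vehicle(self):
        inst = make_instance(("Depot", "A", "B", "C"),
                             cold_demand={"A": 45, "B": 45, "C": 45},
                             vehicles=[Vehicle("Solo", True, "Good", 100, 1000,
                                               0.2, 2)])
        sol = solve(inst, EXACT)
        assert sorted(r.day for r in sol.routes) == [1, 2, 3]


class TestSolve:
    def test_never_worse_than_greedy(self):
        for seed in range(5):
            inst = generate_instance(GeneratorSpec(seed=seed, n_facilities=7,
                                                   n_vehicles=2))
            sol = solve(inst, FAST)
            greedy = greedy_construct(inst, sol.weights, sol.norms)
            assert sol.objective_score <= greedy.objective_score + 1e-9

    def test_deterministic(self):
        inst = generate_instance(GeneratorSpec(seed=3, n_facilities=8,
                                               n_vehicles=2))
        a = solve(inst, FAST)
        b = solve(inst, FAST)
        assert a.routes == b.routes
        assert a.objective_score == b.objective_score

    def test_blocked_leg_never_used_after_cyclone(self):
        inst = apply_emergency(example_instance(), cyclone_scenario())
        for wt in (0, 5, 10):
            sol = solve(inst, EXACT, ObjectiveWeights(wt))
            for r in sol.routes:
                points = ("Center B", *r.stops, "Center B")
                for a, b in zip(points, points[1:]):
                    assert {a, b} != {"Center B", "Center E"}

    def test_respects_time_budget_and_stays_feasible(self):
        inst = generate_instance(GeneratorSpec(seed=11, n_facilities=20,
                                               n_vehicles=3))
        import time

        t0 = time.monotonic()
        sol = solve(inst, SolverConfig(time_budget_seconds=3, branching_width=3))
        assert time.monotonic() - t0 < 10
        assert check_feasible(sol, inst) == []


class TestChecker:
    def test_solver_output_is_clean(self, province):
        assert check_feasible(solve(province, FAST), province) == []

    def test_window_violation_flagged(self):
        from coldroute.solver import Solution

        # 500 km round trip on partially paved roads: 16.7 h in a 10 h window
        inst = make_instance(distances={("Depot", "A"): 500.0})
        r = Route("Truck", 1, ("A",), ("16:00",), RouteMetrics(), AggregatedLoad())
        r = dataclasses.replace(r, metrics=route_metrics(r, inst))
        bad = Solution([r], 0.0, ObjectiveWeights(5), Normalizers())
        codes = {v.code for v in check_feasible(bad, inst)}
        assert "WINDOW" in codes
        # B is unvisited too
        assert "DEMAND_UNMET" in codes

    @pytest.mark.parametrize("mutation", ["drop", "duplicate", "swap_vehicle"])
    def test_perturbed_solutions_are_flagged(self, province, mutation):
        sol = solve(province, FAST)
        assert len(sol.routes) >= 2
        routes = list(sol.routes)
        if mutation == "drop":
            r = routes[1]
            routes[1] = dataclasses.replace(r, stops=r.stops[:-1])
        elif mutation == "duplicate":
            r0, r1 = routes[0], routes[1]
            routes[1] = dataclasses.replace(r1, stops=r1.stops + r0.stops[:1])
        else:
            routes[1] = dataclasses.replace(routes[1], vehicle="Ghost Van")
        sol.routes = routes
        assert check_feasible(sol, province) != []

    def test_unexpected_visit_flagged(self, province):
        sol = solve(province, FAST)
        for p in province.product_names():
            province.demand[("Center G", p)] = 0
        assert any(v.code in ("UNEXPECTED_VISIT",)
                   for v in check_feasible(sol, province))
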