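"""Leg/route metrics, normalization, and the weighted objective."""

import dataclasses

import pytest

from coldroute import (
    ForbiddenLegError,
    Normalizers,
    ObjectiveWeights,
    RoadProfile,
    Vehicle,
    compute_normalizers,
    greedy_construct,
    leg_metrics,
    route_metrics,
    solve,
    weighted_objective,
)
from coldroute.solver import Route, Solution, SolverConfig
from coldroute.objective import RouteMetrics
from coldroute import AggregatedLoad
from conftest import make_instance

GOOD = Vehicle("V", True, "Good", 100, 100, 0.2, 2)
POOR = Vehicle("W", True, "Poor", 100, 100, 0.2, 2)


class TestWeights:
    def test_risk_weight_is_derived(self):
        assert ObjectiveWeights(3).weight_risk == 7
        assert ObjectiveWeights(10).weight_risk == 0

    @pytest.mark.parametrize("bad", [-1, 11, 5.5])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            ObjectiveWeights(bad)


class TestLegMetrics:
    def test_partially_paved_good_vehicle(self):
        inst = make_instance(distances={("Depot", "A"): 40.0},
                             road_classes={("Depot", "A"): "Partially paved"})
        m = leg_metrics("Depot", "A", GOOD, inst.network)
        assert m.hours == pytest.approx(40 / 60)
        assert m.risk == pytest.approx(40.0)
        assert m.km == 40.0

    def test_rough_dirt_poor_vehicle(self):
        inst = make_instance(distances={("Depot", "A"): 30.0},
                             road_classes={("Depot", "A"): "Dirt road (Rough)"})
        m = leg_metrics("Depot", "A", POOR, inst.network)
        assert m.hours == pytest.approx(30 / 25)
        assert m.risk == pytest.approx(30 * (4 + 2))
        assert m.km == 30.0

    def test_self_leg_is_zero(self, tiny):
        m = leg_metrics("A", "A", GOOD, tiny.network)
        assert (m.hours, m.risk, m.km) == (0.0, 0.0, 0.0)

    def test_forbidden_leg_raises(self):
        inst = make_instance(road_classes={("Depot", "A"): "Not accessible"})
        with pytest.raises(ForbiddenLegError):
            leg_metrics("Depot", "A", GOOD, inst.network)

    def test_multiplicative_profile(self):
        profile = RoadProfile(vehicle_risk={"Good": 1.0, "Fair": 2.0, "Poor": 3.0},
                              combine="multiply")
        inst = make_instance(distances={("Depot", "A"): 10.0},
                             road_classes={("Depot", "A"): "Dirt road (Good Quality)"})
        m = leg_metrics("Depot", "A", POOR, inst.network, profile)
        assert m.risk == pytest.approx(10 * 2 * 3)


class TestRouteMetrics:
    def test_two_paved_legs_at_80(self):
        inst = make_instance(distances={("Depot", "A"): 40.0},
                             road_classes={("Depot", "A"): "Fully paved"},
                             vehicles=[GOOD])
        r = Route("V", 1, ("A",), ("08:30",), RouteMetrics(), AggregatedLoad())
        m = route_metrics(r, inst)
        assert m.transit_hours == pytest.approx(1.0)

    def test_fuel_and_per_diem_costs(self):
        # 2 x 40 km legs, 0.2 L/km, 1.5 per liter -> 24.0; crew of 2 at 15
        inst = make_instance(distances={("Depot", "A"): 40.0},
                             vehicles=[GOOD], fuel_price=1.5, per_diem=15.0)
        r = Route("V", 1, ("A",), ("08:40",), RouteMetrics(), AggregatedLoad())
        m = route_metrics(r, inst)
        assert m.fuel_cost == pytest.approx(80 * 0.2 * 1.5)
        assert m.per_diem_cost == pytest.approx(15.0 * 2)

    def test_service_time_counted_per_stop(self):
        inst = make_instance(distances={("Depot", "A"): 40.0},
                             road_classes={("Depot", "A"): "Fully paved"},
                             vehicles=[GOOD], service=0.5)
        r = Route("V", 1, ("A",), ("09:00",), RouteMetrics(), AggregatedLoad())
        assert route_metrics(r, inst).transit_hours == pytest.approx(1.5)

    def test_matches_leg_by_leg_oracle(self, province):
        vehicle = province.vehicles[0]
        stops = ("Center C", "Center D", "Center G", "Center E")
        r = Route(vehicle.name, 1, stops, ("",) * 4, RouteMetrics(), AggregatedLoad())
        m = route_metrics(r, province)
        points = ["Province A", *stops, "Province A"]
        hours = risk = km = 0.0
        for a, b in zip(points, points[1:]):
            lm = leg_metrics(a, b, vehicle, province.network)
            hours += lm.hours
            risk += lm.risk
            km += lm.km
        assert m.transit_hours == pytest.approx(hours)
        assert m.risk == pytest.approx(risk)
        assert m.distance_km == pytest.approx(km)


class TestNormalization:
    def _solution_with(self, instance, transit, risk):
        r = Route("V", 1, ("A",), ("09:00",),
                  RouteMetrics(transit_hours=transit, risk=risk), AggregatedLoad())
        return Solution([r], 0.0, ObjectiveWeights(5), Normalizers())

    def test_norms_are_reference_totals(self, tiny):
        ref = self._solution_with(tiny, 6.0, 240.0)
        assert compute_normalizers(ref) == Normalizers(6.0, 240.0)

    def test_zero_risk_reference_guards_to_one(self, tiny):
        ref = self._solution_with(tiny, 6.0, 0.0)
        assert compute_normalizers(ref).risk_norm == 1.0

    def test_reference_scores_ten_under_its_own_norms(self, tiny):
        ref = self._solution_with(tiny, 6.0, 240.0)
        norms = compute_normalizers(ref)
        for wt in range(11):
            assert weighted_objective(ref, ObjectiveWeights(wt), norms) == \
                pytest.approx(10.0)

    def test_extreme_weights_ignore_the_other_objective(self, tiny):
        norms = Normalizers(2.0, 100.0)
        a = self._solution_with(tiny, 4.0, 500.0)
        b = self._solution_with(tiny, 4.0, 900.0)
        w10 = ObjectiveWeights(10)
        assert weighted_objective(a, w10, norms) == \
            pytest.approx(weighted_objective(b, w10, norms))
        w0 = ObjectiveWeights(0)
        assert weighted_objective(a, w0, norms) == pytest.approx(0 + 10 * 500 / 100)


class TestScaleInvariance:
    def test_scaling_distances_scales_metrics_not_normalized_score(self, province):
        c = 2.5
        scaled = province.copy()
        scaled.network.distance = {
            k: v * c for k, v in province.network.distance.items()}
        # widen the window so the same tours stay feasible
        scaled.parameters = dataclasses.replace(
            scaled.parameters, start_time="00:00", return_time="24:00")
        base = province.copy()
        base.parameters = dataclasses.replace(
            base.parameters, start_time="00:00", return_time="24:00")
        s1 = greedy_construct(base)
        s2 = greedy_construct(scaled)
        assert s2.total_transit_hours == pytest.approx(c * s1.total_transit_hours)
        assert s2.total_risk == pytest.approx(c * s1.total_risk)
        assert s2.total_distance_km == pytest.approx(c * s1.total_distance_km)
        assert s2.total_fuel_cost == pytest.approx(c * s1.total_fuel_cost)
        # normalized score of the pair (solution, its reference) is unchanged
        w = ObjectiveWeights(5)
        n1, n2 = compute_normalizers(s1), compute_normalizers(s2)
        assert weighted_objective(s1, w, n1) == \
            pytest.approx(weighted_objective(s2, w, n2))

    def test_additivity_over_routes(self, province):
        sol = solve(province, SolverConfig(time_budget_seconds=10,
                                           branching_width=3))
        assert sol.total_transit_hours == pytest.approx(
            sum(r.metrics.transit_hours for r in sol.routes))
        assert sol.total_risk == pytest.approx(
            sum(r.metrics.risk for r in sol.routes))
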