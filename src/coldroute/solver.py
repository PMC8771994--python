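"""Route construction and optimization.

The solver builds single-day depot round trips for the facilities with
positive demand, honoring vehicle cold/ambient capacities, road
accessibility, the daily time window, and even use of the available fleet
(route counts per vehicle may differ by at most one).

Two mechanisms cooperate:

* an *indexing rule* that greedily constructs a feasible solution in
  milliseconds — a vehicle index decides which vehicle opens the next
  route, and a facility index (the normalized marginal objective of the
  candidate leg, with a hard feasibility filter) decides which facility to
  visit next, recalculated after every insertion;
* an *anytime* depth-first branch-and-bound that uses the greedy solution
  as incumbent, branches on the best few index extensions (plus closing
  the route), prunes with an admissible per-facility entering-cost bound,
  and returns the best incumbent when the time budget expires.  With
  ``branching_width="all"`` and a generous budget the search is exhaustive
  and the result is a certified optimum under the evenness constraint.

The solver is deterministic: all tie-breaks are lexicographic and no
randomness is used.
"""

from __future__ import annotations

import heapq
import math
import time as _time
from dataclasses import dataclass, field

from .instance import (
    AggregatedLoad,
    Instance,
    Vehicle,
    aggregate_demand,
    format_clock,
    visit_set,
)
from .objective import (
    Normalizers,
    ObjectiveWeights,
    RoadProfile,
    RouteMetrics,
    compute_normalizers,
    route_metrics,
    weighted_objective,
)

__all__ = [
    "SolverConfig",
    "Route",
    "Solution",
    "PartialSolution",
    "Violation",
    "InfeasibleInstanceError",
    "facility_index",
    "vehicle_index",
    "greedy_construct",
    "solve",
    "check_feasible",
]

_EPS = 1e-9
_COND_RANK = {"Good": 0, "Fair": 1, "Poor": 2}


class InfeasibleInstanceError(RuntimeError):
    """Some facility with demand can never be served by any route."""


@dataclass(frozen=True)
class SolverConfig:
    time_budget_seconds: float = 120.0
    branching_width: int | str = 3  # positive int, or "all" for exact search
    seed: int = 0  # reserved for generator modules; the solver is deterministic

    def __post_init__(self):
        if self.branching_width != "all" and (
            not isinstance(self.branching_width, int) or self.branching_width < 1
        ):
            raise ValueError("branching_width must be a positive integer or 'all'")
        if self.time_budget_seconds <= 0:
            raise ValueError("time_budget_seconds must be > 0")


@dataclass(frozen=True)
class Route:
    """One vehicle's depot-to-depot tour on one day."""

    vehicle: str
    day: int
    stops: tuple[str, ...]
    departure_times: tuple[str, ...]  # clock time leaving each stop
    metrics: RouteMetrics
    load: AggregatedLoad


@dataclass
class Solution:
    routes: list[Route]
    objective_score: float
    weights: ObjectiveWeights
    norms: Normalizers
    search_completed: bool = False

    @property
    def total_transit_hours(self) -> float:
        return sum(r.metrics.transit_hours for r in self.routes)

    @property
    def total_risk(self) -> float:
        return sum(r.metrics.risk for r in self.routes)

    @property
    def total_distance_km(self) -> float:
        return sum(r.metrics.distance_km for r in self.routes)

    @property
    def total_fuel_cost(self) -> float:
        return sum(r.metrics.fuel_cost for r in self.routes)

    @property
    def total_per_diem_cost(self) -> float:
        return sum(r.metrics.per_diem_cost for r in self.routes)


@dataclass(frozen=True)
class Violation:
    code: str
    location: str
    message: str


# ---------------------------------------------------------------------------
# Compiled instance: index-based matrices for the search inner loop
# ---------------------------------------------------------------------------

class _Compiled:
    def __init__(self, instance: Instance, profile: RoadProfile):
        p = instance.parameters
        self.instance = instance
        self.profile = profile
        self.visit = sorted(visit_set(instance))
        self.n = len(self.visit)
        self.depot_i = self.n
        self.names = self.visit + [p.depot_name]
        self.window = p.window_hours
        self.service = p.service_hours_per_stop
        self.start = p.start_hours

        net = instance.network
        m = self.n + 1
        inf = math.inf
        self.t = [[inf] * m for _ in range(m)]
        self.dist = [[0.0] * m for _ in range(m)]
        self.acc = [[False] * m for _ in range(m)]
        self.risk_by_cond = {c: [[inf] * m for _ in range(m)] for c in _COND_RANK}
        for i in range(m):
            for j in range(m):
                if i == j:
                    self.t[i][j] = 0.0
                    self.acc[i][j] = True
                    for c in _COND_RANK:
                        self.risk_by_cond[c][i][j] = 0.0
                    continue
                a, b = self.names[i], self.names[j]
                if not net.is_accessible(a, b):
                    continue
                cls = net.get_class(a, b)
                d = net.get_distance(a, b)
                self.acc[i][j] = True
                self.dist[i][j] = d
                self.t[i][j] = d / profile.speeds[cls]
                for c in _COND_RANK:
                    self.risk_by_cond[c][i][j] = d * profile.risk_per_km(cls, c)

        self.loads = [aggregate_demand(instance, f) for f in self.visit]

        # available vehicles, deterministic order
        self.vehicles: list[Vehicle] = sorted(
            instance.available_vehicles(), key=lambda v: v.name
        )
        self.veh_risk = [self.risk_by_cond[v.condition] for v in self.vehicles]
        conds = {v.condition for v in self.vehicles}
        best = min(conds, key=lambda c: _COND_RANK[c]) if conds else "Good"
        self.min_risk = self.risk_by_cond[best]

        # admissible lower bound on the remaining time from each facility to
        # the depot (shortest accessible path, service charged per hop)
        self.ret_lb = self._dijkstra_to_depot()

    def _dijkstra_to_depot(self) -> list[float]:
        m = self.n + 1
        distx = [math.inf] * m
        distx[self.depot_i] = 0.0
        pq = [(0.0, self.depot_i)]
        while pq:
            d, u = heapq.heappop(pq)
            if d > distx[u]:
                continue
            for v in range(m):
                if v == u or not self.acc[u][v]:
                    continue
                # hop v->u costs travel plus service at v if v is a delivery
                nd = d + self.t[v][u] + (self.service if u != self.depot_i else 0.0)
                if nd < distx[v] - 1e-15:
                    distx[v] = nd
                    heapq.heappush(pq, (nd, v))
        return distx


def _cond_key(v: Vehicle) -> tuple:
    return (-(v.cold_capacity + v.ambient_capacity), _COND_RANK.get(v.condition, 9), v.name)


# ---------------------------------------------------------------------------
# PartialSolution and the two indices
# ---------------------------------------------------------------------------

@dataclass
class PartialSolution:
    """State of route construction: closed routes plus one open route.

    Exposes the data both indices read: routes-per-vehicle counts, the open
    route's position, elapsed time and remaining capacities, and the set of
    unvisited facilities.
    """

    compiled: _Compiled
    closed: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)
    open_vehicle: int | None = None
    open_stops: list[int] = field(default_factory=list)
    elapsed: float = 0.0
    rem_cold: float = 0.0
    rem_ambient: float = 0.0
    unvisited: set[int] = field(default_factory=set)
    partial_score: float = 0.0

    @classmethod
    def initial(cls, instance: Instance, profile: RoadProfile | None = None,
                compiled: _Compiled | None = None) -> "PartialSolution":
        c = compiled or _Compiled(instance, profile or RoadProfile())
        return cls(compiled=c, counts=[0] * len(c.vehicles),
                   unvisited=set(range(c.n)))

    @property
    def current(self) -> int:
        return self.open_stops[-1] if self.open_stops else self.compiled.depot_i

    def open_route(self, vehicle_i: int) -> None:
        v = self.compiled.vehicles[vehicle_i]
        self.open_vehicle = vehicle_i
        self.open_stops = []
        self.elapsed = 0.0
        self.rem_cold = v.cold_capacity
        self.rem_ambient = v.ambient_capacity


def vehicle_index(state: PartialSolution, vehicle: Vehicle) -> tuple:
    """Rank key deciding which vehicle opens the next route.

    Lexicographic: fewest routes already assigned, then total capacity
    descending, then condition Good < Fair < Poor, then name.  Giving each
    new route to the lowest key enforces even fleet use.
    """
    c = state.compiled
    vi = next(i for i, v in enumerate(c.vehicles) if v.name == vehicle.name)
    return (state.counts[vi], *_cond_key(vehicle))


def _extension(state: PartialSolution, cand: int,
               weights: ObjectiveWeights | None,
               norms: Normalizers | None):
    """(cost, leg_hours, leg_risk) for extending the open route, or None.

    Infeasible when the leg is inaccessible, the candidate's load overflows
    remaining capacity, or the elapsed time plus the leg, the service stop
    and a lower bound on the accessible return to the depot would exceed
    the daily window.  With ``norms`` None (bootstrap pass) the cost is the
    raw leg travel time.
    """
    c = state.compiled
    u = state.current
    if not c.acc[u][cand]:
        return None
    load = c.loads[cand]
    if load.cold_volume > state.rem_cold + _EPS:
        return None
    if load.ambient_volume > state.rem_ambient + _EPS:
        return None
    leg_t = c.t[u][cand] + c.service
    if state.elapsed + leg_t + c.ret_lb[cand] > c.window + _EPS:
        return None
    if state.open_vehicle is None:
        risk_m = c.min_risk
    else:
        risk_m = c.veh_risk[state.open_vehicle]
    leg_r = risk_m[u][cand]
    if norms is None:
        cost = c.t[u][cand]
    else:
        w = weights or ObjectiveWeights()
        cost = w.weight_time * leg_t / norms.time_norm + \
            w.weight_risk * leg_r / norms.risk_norm
    return (cost, leg_t, leg_r)


def facility_index(state: PartialSolution, candidate: str,
                   weights: ObjectiveWeights | None = None,
                   norms: Normalizers | None = None):
    """Priority score for visiting ``candidate`` next, or None if infeasible.

    The score is the normalized marginal objective of the candidate leg:
    ``W_t * dt/time_norm + W_p * drisk/risk_norm``.  Lower is better.
    """
    c = state.compiled
    try:
        cand = c.visit.index(candidate)
    except ValueError:
        raise KeyError(f"{candidate!r} is not an unvisited demand facility")
    if cand not in state.unvisited:
        raise KeyError(f"{candidate!r} already visited")
    ext = _extension(state, cand, weights, norms)
    return None if ext is None else ext[0]


# ---------------------------------------------------------------------------
# Greedy construction
# ---------------------------------------------------------------------------

def _vehicle_candidates(c: _Compiled, counts: list[int]) -> list[int]:
    mn = min(counts)
    order = sorted((i for i in range(len(counts)) if counts[i] == mn),
                   key=lambda i: _cond_key(c.vehicles[i]))
    return order


def _precheck(c: _Compiled) -> None:
    for j in range(c.n):
        load = c.loads[j]
        if not any(load.cold_volume <= v.cold_capacity + _EPS
                   and load.ambient_volume <= v.ambient_capacity + _EPS
                   for v in c.vehicles):
            raise InfeasibleInstanceError(
                f"demand at {c.visit[j]!r} exceeds every vehicle's capacity")
        if not any(c.acc[i][j] for i in range(c.n + 1) if i != j):
            raise InfeasibleInstanceError(
                f"{c.visit[j]!r} has no accessible road at all")
        if c.ret_lb[j] > c.window + _EPS or not any(
            c.acc[i][j] and c.t[i][j] + c.service + c.ret_lb[j] <= c.window + _EPS
            for i in range(c.n + 1) if i != j
        ):
            raise InfeasibleInstanceError(
                f"a round trip serving {c.visit[j]!r} cannot fit the daily window")


def _greedy_route(c: _Compiled, state: PartialSolution, vi: int,
                  weights, norms) -> tuple[int, ...] | None:
    """Build one route for vehicle ``vi`` by repeated best-index insertion.

    Dead ends (no feasible extension and no accessible direct return) are
    resolved by dropping the last stop and barring it from this route.
    """
    D = c.depot_i
    state.open_route(vi)
    tabu: set[int] = set()
    history: list[tuple[int, float, float, float]] = []
    while True:
        best = None
        for cand in sorted(state.unvisited - tabu):
            ext = _extension(state, cand, weights, norms)
            if ext is None:
                continue
            if best is None or ext[0] < best[1] - 1e-15:
                best = (cand, ext[0], ext[1], ext[2])
        if best is not None:
            cand, _, leg_t, _ = best
            history.append((cand, state.elapsed, state.rem_cold, state.rem_ambient))
            state.open_stops.append(cand)
            state.unvisited.discard(cand)
            state.elapsed += leg_t
            load = c.loads[cand]
            state.rem_cold -= load.cold_volume
            state.rem_ambient -= load.ambient_volume
            continue
        # no extension: try to close
        u = state.current
        if state.open_stops and c.acc[u][D] and \
                state.elapsed + c.t[u][D] <= c.window + _EPS:
            stops = tuple(state.open_stops)
            state.open_vehicle = None
            state.open_stops = []
            state.elapsed = 0.0
            return stops
        if not state.open_stops:
            state.open_vehicle = None
            return None
        # dead end: backtrack one stop
        cand, el, rc, ra = history.pop()
        state.open_stops.pop()
        state.unvisited.add(cand)
        state.elapsed, state.rem_cold, state.rem_ambient = el, rc, ra
        tabu.add(cand)


def _greedy_routes(c: _Compiled, weights, norms) -> list[tuple[int, tuple[int, ...]]]:
    state = PartialSolution.initial(c.instance, compiled=c)
    routes: list[tuple[int, tuple[int, ...]]] = []
    while state.unvisited:
        built = None
        for vi in _vehicle_candidates(c, state.counts):
            stops = _greedy_route(c, state, vi, weights, norms)
            if stops:
                built = (vi, stops)
                break
        if built is None:
            raise InfeasibleInstanceError(
                "greedy construction cannot serve the remaining facilities "
                "under even vehicle use")
        routes.append(built)
        state.counts[built[0]] += 1
    return routes


def _assemble(c: _Compiled, raw: list[tuple[int, tuple[int, ...]]],
              weights: ObjectiveWeights, norms: Normalizers,
              completed: bool = False) -> Solution:
    instance = c.instance
    day_count = [0] * len(c.vehicles)
    routes: list[Route] = []
    for vi, stops in raw:
        day_count[vi] += 1
        v = c.vehicles[vi]
        names = tuple(c.visit[s] for s in stops)
        # departure time leaving each stop
        deps = []
        clock = c.start
        prev = c.depot_i
        for s in stops:
            clock += c.t[prev][s] + c.service
            deps.append(format_clock(clock))
            prev = s
        load = AggregatedLoad()
        for s in stops:
            load = load + c.loads[s]
        r = Route(vehicle=v.name, day=day_count[vi], stops=names,
                  departure_times=tuple(deps),
                  metrics=RouteMetrics(), load=load)
        r = Route(vehicle=r.vehicle, day=r.day, stops=r.stops,
                  departure_times=r.departure_times,
                  metrics=route_metrics(r, instance, c.profile), load=load)
        routes.append(r)
    routes.sort(key=lambda r: (r.vehicle, r.day))
    sol = Solution(routes=routes, objective_score=0.0, weights=weights,
                   norms=norms, search_completed=completed)
    sol.objective_score = weighted_objective(sol, weights, norms)
    return sol


def greedy_construct(instance: Instance,
                     weights: ObjectiveWeights | None = None,
                     norms: Normalizers | None = None,
                     profile: RoadProfile | None = None) -> Solution:
    """Construct a feasible solution with the indexing rule alone.

    With ``norms`` None this is the bootstrap pass: the facility index is
    the raw leg travel time, and the returned solution serves as the
    normalization reference.  Raises :class:`InfeasibleInstanceError` when
    some facility can never be served.
    """
    c = _Compiled(instance, profile or RoadProfile())
    w = weights or ObjectiveWeights(instance.parameters.weight_time)
    if c.n == 0:
        return Solution([], 0.0, w, norms or Normalizers(), search_completed=True)
    _precheck(c)
    raw = _greedy_routes(c, w, norms)
    return _assemble(c, raw, w, norms or compute_normalizers(
        _assemble(c, raw, w, Normalizers())), completed=False)


# ---------------------------------------------------------------------------
# Branch and bound
# ---------------------------------------------------------------------------

class _Timeout(Exception):
    pass


def solve(instance: Instance, config: SolverConfig | None = None,
          weights: ObjectiveWeights | None = None,
          profile: RoadProfile | None = None) -> Solution:
    """Optimize routes with anytime depth-first branch-and-bound.

    The incumbent starts as the greedy solution; the search branches on the
    ``branching_width`` best facility-index extensions of the open route
    (plus closing it, and — when opening a new route — each distinct
    minimum-count vehicle), prunes with an admissible entering-cost lower
    bound, and stops at budget expiry, returning the best incumbent.  With
    ``branching_width="all"`` and enough budget the optimum under the
    evenness constraint is certified (``search_completed`` is True).
    """
    profile = profile or RoadProfile()
    c = _Compiled(instance, profile)
    w = weights or ObjectiveWeights(instance.parameters.weight_time)
    if config is None:
        config = SolverConfig(
            time_budget_seconds=instance.parameters.time_budget_seconds)
    if c.n == 0:
        return Solution([], 0.0, w, Normalizers(), search_completed=True)
    _precheck(c)

    # normalization reference: the pure-time greedy pass
    try:
        ref_raw = _greedy_routes(c, None, None)
        norms = compute_normalizers(_assemble(c, ref_raw, w, Normalizers()))
    except InfeasibleInstanceError:
        ref_raw, norms = None, Normalizers()

    wt, wp = float(w.weight_time), float(w.weight_risk)
    tn, rn = norms.time_norm, norms.risk_norm
    D, n, svc, window = c.depot_i, c.n, c.service, c.window
    t, acc, loads, ret_lb = c.t, c.acc, c.loads, c.ret_lb

    def leg_cost(risk_m, u, v):
        return wt * (t[u][v] + (svc if v != D else 0.0)) / tn + wp * risk_m[u][v] / rn

    # admissible per-facility lower bound: cheapest accessible entering leg
    enter = [math.inf] * n
    for j in range(n):
        for i in range(n + 1):
            if i != j and acc[i][j]:
                cost = wt * (t[i][j] + svc) / tn + wp * c.min_risk[i][j] / rn
                if cost < enter[j]:
                    enter[j] = cost

    # incumbent from greedy
    best_raw: list[tuple[int, tuple[int, ...]]] | None = None
    best_score = math.inf
    try:
        g_raw = _greedy_routes(c, w, norms)
        best_raw = g_raw
        best_score = sum(
            sum(leg_cost(c.veh_risk[vi], a, b)
                for a, b in zip((D, *stops), (*stops, D)))
            for vi, stops in g_raw)
    except InfeasibleInstanceError:
        pass

    width = config.branching_width
    deadline = _time.monotonic() + config.time_budget_seconds
    tick = 0
    counts = [0] * len(c.vehicles)
    closed: list[tuple[int, tuple[int, ...]]] = []
    unvisited = set(range(n))
    completed = True

    def vehicle_branches() -> list[int]:
        cands = _vehicle_candidates(c, counts)
        if width == "all":
            seen, out = set(), []
            for vi in cands:
                v = c.vehicles[vi]
                sig = (v.cold_capacity, v.ambient_capacity, v.condition)
                if sig not in seen:
                    seen.add(sig)
                    out.append(vi)
            return out
        return cands[:1]

    def dfs(vi: int | None, stops: tuple[int, ...], u: int, elapsed: float,
            rc: float, ra: float, partial: float):
        nonlocal best_raw, best_score, tick, completed
        tick += 1
        if tick & 0x1FF == 0 and _time.monotonic() > deadline:
            raise _Timeout
        lb = partial + sum(enter[j] for j in unvisited)
        if lb >= best_score - 1e-12:
            return
        if vi is None:
            if not unvisited:
                if partial < best_score - 1e-12:
                    best_score = partial
                    best_raw = list(closed)
                return
            for nvi in vehicle_branches():
                v = c.vehicles[nvi]
                counts[nvi] += 1
                dfs(nvi, (), D, 0.0, v.cold_capacity, v.ambient_capacity, partial)
                counts[nvi] -= 1
            return
        # extensions of the open route
        risk_m = c.veh_risk[vi]
        exts = []
        for cand in unvisited:
            if not acc[u][cand]:
                continue
            load = loads[cand]
            if load.cold_volume > rc + _EPS or load.ambient_volume > ra + _EPS:
                continue
            leg_t = t[u][cand] + svc
            if elapsed + leg_t + ret_lb[cand] > window + _EPS:
                continue
            exts.append((leg_cost(risk_m, u, cand), cand, leg_t))
        exts.sort()
        if width != "all":
            exts = exts[:width]
        for cost, cand, leg_t in exts:
            load = loads[cand]
            unvisited.discard(cand)
            dfs(vi, stops + (cand,), cand, elapsed + leg_t,
                rc - load.cold_volume, ra - load.ambient_volume, partial + cost)
            unvisited.add(cand)
        # close the route (only meaningful with at least one stop)
        if stops and acc[u][D] and elapsed + t[u][D] <= window + _EPS:
            closed.append((vi, stops))
            dfs(None, (), D, 0.0, 0.0, 0.0, partial + leg_cost(risk_m, u, D))
            closed.pop()

    try:
        dfs(None, (), D, 0.0, 0.0, 0.0, 0.0)
    except _Timeout:
        completed = False

    if best_raw is None:
        raise InfeasibleInstanceError(
            "no feasible assignment of routes to vehicles exists under the "
            "daily window, capacity, accessibility and evenness constraints")
    return _assemble(c, best_raw, w, norms, completed=completed)


# ---------------------------------------------------------------------------
# Feasibility checking
# ---------------------------------------------------------------------------

def check_feasible(solution: Solution, instance: Instance,
                   profile: RoadProfile | None = None) -> list[Violation]:
    """Independently re-check every constraint of a solution.

    Returns an empty list iff the solution satisfies: the daily window per
    route, depot round trips, demand met (every demand facility visited),
    exactly-once visits, even vehicle use, cold/ambient capacities, and
    accessibility of every leg.
    """
    profile = profile or RoadProfile()
    p = instance.parameters
    out: list[Violation] = []
    must = visit_set(instance)
    seen: dict[str, int] = {}
    avail = {v.name: v for v in instance.available_vehicles()}
    counts = {name: 0 for name in avail}

    for ri, r in enumerate(solution.routes):
        loc = f"route[{ri}]"
        if r.vehicle not in avail:
            out.append(Violation("VEHICLE_UNAVAILABLE", loc,
                                 f"vehicle {r.vehicle!r} is not available"))
        else:
            counts[r.vehicle] += 1
        if not r.stops:
            out.append(Violation("EMPTY_ROUTE", loc, "route has no stops"))
            continue
        for s in r.stops:
            if s == p.depot_name:
                out.append(Violation("DEPOT_AS_STOP", loc,
                                     "depot listed as a delivery stop"))
            seen[s] = seen.get(s, 0) + 1
        points = [p.depot_name, *r.stops, p.depot_name]
        hours = 0.0
        for a, b in zip(points, points[1:]):
            if not instance.network.is_accessible(a, b):
                out.append(Violation("FORBIDDEN_LEG", loc,
                                     f"leg {a!r} -> {b!r} is not accessible"))
            else:
                cls = instance.network.get_class(a, b)
                hours += instance.network.get_distance(a, b) / profile.speeds[cls]
        hours += p.service_hours_per_stop * len(r.stops)
        if hours > p.window_hours + 1e-6:
            out.append(Violation("WINDOW", loc,
                                 f"route takes {hours:.2f} h, window is "
                                 f"{p.window_hours:.2f} h"))
        veh = avail.get(r.vehicle)
        if veh is not None:
            load = AggregatedLoad()
            for s in r.stops:
                if s in {f.name for f in instance.facilities}:
                    load = load + aggregate_demand(instance, s)
            if load.cold_volume > veh.cold_capacity + 1e-6:
                out.append(Violation("CAPACITY_COLD", loc,
                                     f"cold load {load.cold_volume:.1f} L exceeds "
                                     f"{veh.cold_capacity:.1f} L"))
            if load.ambient_volume > veh.ambient_capacity + 1e-6:
                out.append(Violation("CAPACITY_AMBIENT", loc,
                                     f"ambient load {load.ambient_volume:.1f} L "
                                     f"exceeds {veh.ambient_capacity:.1f} L"))

    for name, k in seen.items():
        if k > 1:
            out.append(Violation("MULTIPLE_VISITS", f"facility {name}",
                                 f"visited {k} times"))
        if name not in must and name != p.depot_name:
            out.append(Violation("UNEXPECTED_VISIT", f"facility {name}",
                                 "facility has no demand but is visited"))
    for name in sorted(must - set(seen)):
        out.append(Violation("DEMAND_UNMET", f"facility {name}",
                             "facility with demand is never visited"))
    if counts and solution.routes:
        if max(counts.values()) - min(counts.values()) > 1:
            out.append(Violation("UNEVEN_USE", "fleet",
                                 f"route counts {counts} differ by more than 1"))
    return out
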