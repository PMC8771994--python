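"""Brute-force exact solver for small instances.

Used as an independent correctness oracle for the branch-and-bound
solver: it enumerates every ordered partition of the demand facilities
into route sequences (a permutation of the facilities cut into contiguous
blocks), every evenness-respecting assignment of those routes to the
available vehicles, discards assignments that violate capacity, the daily
window or road accessibility, and returns the feasible solution with the
minimum weighted objective.  Ties are broken by the lexicographic
representation of the route list.

This is deliberately naive and shares no search code with the solver;
only the leg arithmetic (via the objective module) is common.  Size is
capped at 8 facilities and 3 available vehicles.
"""

from __future__ import annotations

from itertools import permutations

from .instance import Instance, visit_set
from .objective import (
    Normalizers,
    ObjectiveWeights,
    RoadProfile,
)
from .solver import InfeasibleInstanceError, Solution, _Compiled, _assemble

__all__ = ["SizeLimitError", "enumerate_optimal"]

MAX_FACILITIES = 8
MAX_VEHICLES = 3


class SizeLimitError(ValueError):
    """Instance too large for exhaustive enumeration."""


def _compositions(n: int):
    """Yield tuples of positive block lengths summing to n."""
    if n == 0:
        yield ()
        return
    for first in range(1, n + 1):
        for rest in _compositions(n - first):
            yield (first, *rest)


def _even_assignments(n_routes: int, n_vehicles: int):
    """Yield vehicle-index tuples with route counts differing by <= 1."""

    def rec(prefix, counts):
        k = len(prefix)
        if k == n_routes:
            if max(counts) - min(counts) <= 1:
                yield tuple(prefix)
            return
        for v in range(n_vehicles):
            counts[v] += 1
            # feasible completion requires remaining routes to lift the
            # minimum within 1 of the maximum
            remaining = n_routes - k - 1
            need = sum(max(0, max(counts) - 1 - c) for c in counts)
            if need <= remaining:
                yield from rec(prefix + [v], counts)
            counts[v] -= 1

    yield from rec([], [0] * n_vehicles)


def enumerate_optimal(instance: Instance,
                      weights: ObjectiveWeights | None = None,
                      norms: Normalizers | None = None,
                      profile: RoadProfile | None = None
                      ) -> tuple[Solution, float]:
    """Exhaustively find the optimal solution and its objective score.

    ``norms`` should be the same normalizers the solver under test uses so
    that scores are directly comparable; they default to 1/1.  Raises
    :class:`SizeLimitError` above 8 facilities or 3 available vehicles and
    :class:`InfeasibleInstanceError` when no feasible solution exists.
    """
    profile = profile or RoadProfile()
    w = weights or ObjectiveWeights(instance.parameters.weight_time)
    norms = norms or Normalizers()
    c = _Compiled(instance, profile)
    n = c.n
    if n > MAX_FACILITIES or len(c.vehicles) > MAX_VEHICLES:
        raise SizeLimitError(
            f"{n} facilities / {len(c.vehicles)} vehicles exceed the "
            f"enumeration bounds ({MAX_FACILITIES}/{MAX_VEHICLES})")
    if n == 0:
        sol = _assemble(c, [], w, norms, completed=True)
        return sol, sol.objective_score
    if not c.vehicles:
        raise InfeasibleInstanceError("no available vehicle")

    D = c.depot_i
    wt, wp = float(w.weight_time), float(w.weight_risk)
    tn, rn = norms.time_norm, norms.risk_norm

    # cache per (route sequence, vehicle index): feasible? normalized score
    cache: dict[tuple, float | None] = {}

    def route_score(seq: tuple[int, ...], vi: int) -> float | None:
        key = (seq, vi)
        if key in cache:
            return cache[key]
        v = c.vehicles[vi]
        cold = sum(c.loads[s].cold_volume for s in seq)
        amb = sum(c.loads[s].ambient_volume for s in seq)
        score: float | None
        if cold > v.cold_capacity + 1e-9 or amb > v.ambient_capacity + 1e-9:
            score = None
        else:
            hours = risk = 0.0
            risk_m = c.veh_risk[vi]
            ok = True
            for a, b in zip((D, *seq), (*seq, D)):
                if not c.acc[a][b]:
                    ok = False
                    break
                hours += c.t[a][b]
                risk += risk_m[a][b]
            hours += c.service * len(seq)
            if not ok or hours > c.window + 1e-9:
                score = None
            else:
                score = wt * hours / tn + wp * risk / rn
        cache[key] = score
        return score

    nv = len(c.vehicles)
    best_score = None
    best_routes = None
    best_repr = None
    facilities = list(range(n))
    for perm in permutations(facilities):
        for comp in _compositions(n):
            routes = []
            pos = 0
            for size in comp:
                routes.append(tuple(perm[pos:pos + size]))
                pos += size
            # per-route per-vehicle feasibility screen
            per_route = [[route_score(r, vi) for vi in range(nv)] for r in routes]
            if any(all(s is None for s in scores) for scores in per_route):
                continue
            for assign in _even_assignments(len(routes), nv):
                total = 0.0
                ok = True
                for scores, vi in zip(per_route, assign):
                    s = scores[vi]
                    if s is None:
                        ok = False
                        break
                    total += s
                if not ok:
                    continue
                rep = tuple(sorted(
                    (c.vehicles[vi].name, r) for r, vi in zip(routes, assign)))
                if best_score is None or total < best_score - 1e-12 or (
                    abs(total - best_score) <= 1e-12 and rep < best_repr
                ):
                    best_score = total
                    best_repr = rep
                    best_routes = [(vi, r) for r, vi in zip(routes, assign)]
    if best_score is None:
        raise InfeasibleInstanceError("no feasible solution exists")
    # order routes per vehicle for day numbering
    best_routes.sort(key=lambda vr: (c.vehicles[vr[0]].name, vr[1]))
    sol = _assemble(c, best_routes, w, norms, completed=True)
    return sol, best_score
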