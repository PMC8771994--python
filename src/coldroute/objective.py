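"""Route metrics and the weighted time/risk objective.

Two objectives are combined by a user weight: total transit time of all
routes, and a spoilage-risk penalty accumulated per km from road condition
and vehicle condition.  Both are normalized by the totals of a reference
solution so that a weight pair like 5/5 gives the two objectives equal
influence regardless of their natural scales.

The risk model is deliberately simple: each road class carries a risk
factor per km, each vehicle condition an addend per km, and a leg of d km
contributes ``d * (road_factor + vehicle_addend)`` risk units.  Longer
exposure on worse roads in worse vehicles scales the chance of a
temperature excursion linearly.  Speeds and factors are configurable; the
defaults below are documented planning values, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .instance import (
    NOT_ACCESSIBLE,
    PASSABLE_CLASSES,
    VEHICLE_CONDITIONS,
    Instance,
    Vehicle,
    RoadNetwork,
)

if TYPE_CHECKING:  # pragma: no cover
    from .solver import Route, Solution

__all__ = [
    "ObjectiveWeights",
    "RoadProfile",
    "LegMetrics",
    "RouteMetrics",
    "Normalizers",
    "ForbiddenLegError",
    "leg_metrics",
    "route_metrics",
    "compute_normalizers",
    "weighted_objective",
]


class ForbiddenLegError(ValueError):
    """A route leg uses a road marked Not accessible."""


@dataclass(frozen=True)
class ObjectiveWeights:
    """User weight for transit time; the risk weight is always derived.

    ``weight_time`` (W_t) is an integer 0–10 and ``weight_risk`` (W_p) is
    ``10 - weight_time`` — never entered separately.  At 10 the model
    optimizes transit time only; at 0, risk only.
    """

    weight_time: int = 5

    def __post_init__(self):
        if not (isinstance(self.weight_time, int) and 0 <= self.weight_time <= 10):
            raise ValueError(f"weight_time must be an integer 0..10, got {self.weight_time!r}")

    @property
    def weight_risk(self) -> int:
        return 10 - self.weight_time


# Default speeds (km/h) and per-km risk factors by road class, and per-km
# risk addends by vehicle condition.  Combine mode "add" sums road factor
# and vehicle addend; "multiply" multiplies them (then Good should be 1).
_DEFAULT_SPEEDS = {
    "Fully paved": 80.0,
    "Partially paved": 60.0,
    "Dirt road (Good Quality)": 40.0,
    "Dirt road (Rough)": 25.0,
}
_DEFAULT_ROAD_RISK = {
    "Fully paved": 0.0,
    "Partially paved": 1.0,
    "Dirt road (Good Quality)": 2.0,
    "Dirt road (Rough)": 4.0,
}
_DEFAULT_VEHICLE_RISK = {"Good": 0.0, "Fair": 1.0, "Poor": 2.0}


@dataclass(frozen=True)
class RoadProfile:
    """Travel speeds and risk coefficients per road class and vehicle condition."""

    speeds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SPEEDS))
    road_risk: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ROAD_RISK))
    vehicle_risk: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_VEHICLE_RISK))
    combine: str = "add"  # "add" or "multiply"

    def __post_init__(self):
        for cls in PASSABLE_CLASSES:
            if self.speeds.get(cls, 0) <= 0:
                raise ValueError(f"speed for {cls!r} must be > 0")
            if self.road_risk.get(cls, -1) < 0:
                raise ValueError(f"road risk factor for {cls!r} must be >= 0")
        for cond in VEHICLE_CONDITIONS:
            if self.vehicle_risk.get(cond, -1) < 0:
                raise ValueError(f"vehicle risk addend for {cond!r} must be >= 0")
        if self.combine not in ("add", "multiply"):
            raise ValueError(f"combine must be 'add' or 'multiply', got {self.combine!r}")

    def risk_per_km(self, road_class: str, condition: str) -> float:
        r = self.road_risk[road_class]
        v = self.vehicle_risk[condition]
        return r * v if self.combine == "multiply" else r + v

    @classmethod
    def from_dict(cls, data: dict) -> "RoadProfile":
        speeds = dict(_DEFAULT_SPEEDS)
        road = dict(_DEFAULT_ROAD_RISK)
        veh = dict(_DEFAULT_VEHICLE_RISK)
        speeds.update(data.get("speeds", {}))
        road.update(data.get("road_risk", {}))
        veh.update(data.get("vehicle_risk", {}))
        return cls(speeds=speeds, road_risk=road, vehicle_risk=veh,
                   combine=data.get("combine", "add"))

    @classmethod
    def from_file(cls, path) -> "RoadProfile":
        """Load overrides from a YAML (or JSON — YAML superset) file."""
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass(frozen=True)
class LegMetrics:
    hours: float
    risk: float
    km: float


@dataclass(frozen=True)
class RouteMetrics:
    transit_hours: float = 0.0
    risk: float = 0.0
    distance_km: float = 0.0
    fuel_cost: float = 0.0
    per_diem_cost: float = 0.0


@dataclass(frozen=True)
class Normalizers:
    """Reference totals dividing each objective; zero references become 1."""

    time_norm: float = 1.0
    risk_norm: float = 1.0

    def __post_init__(self):
        if self.time_norm <= 0 or self.risk_norm <= 0:
            raise ValueError("normalizers must be strictly positive")


def leg_metrics(i: str, j: str, vehicle: Vehicle, network: RoadNetwork,
                profile: RoadProfile | None = None) -> LegMetrics:
    """Travel time, risk and distance of the direct leg from i to j.

    Raises :class:`ForbiddenLegError` when the road is not accessible.
    """
    profile = profile or RoadProfile()
    if i == j:
        return LegMetrics(0.0, 0.0, 0.0)
    cls = network.get_class(i, j)
    if cls == NOT_ACCESSIBLE:
        raise ForbiddenLegError(f"leg {i!r} -> {j!r} is not accessible")
    d = network.get_distance(i, j)
    hours = d / profile.speeds[cls]
    risk = d * profile.risk_per_km(cls, vehicle.condition)
    return LegMetrics(hours, risk, d)


def route_metrics(route: "Route", instance: Instance,
                  profile: RoadProfile | None = None) -> RouteMetrics:
    """Sum leg metrics over a depot-to-depot tour and attach costs.

    Transit time includes the configured service time at each delivery
    stop.  Fuel cost is distance x consumption x fuel price; per diem is
    charged once per route (a single crew-day) at rate x crew size.
    """
    profile = profile or RoadProfile()
    p = instance.parameters
    vehicle = next(v for v in instance.vehicles if v.name == route.vehicle)
    depot = p.depot_name
    points = [depot, *route.stops, depot]
    hours = risk = km = 0.0
    for a, b in zip(points, points[1:]):
        m = leg_metrics(a, b, vehicle, instance.network, profile)
        hours += m.hours
        risk += m.risk
        km += m.km
    hours += p.service_hours_per_stop * len(route.stops)
    return RouteMetrics(
        transit_hours=hours,
        risk=risk,
        distance_km=km,
        fuel_cost=km * vehicle.fuel_consumption * p.fuel_price,
        per_diem_cost=p.per_diem_rate * vehicle.crew_size,
    )


def compute_normalizers(reference: "Solution") -> Normalizers:
    """Normalizers from a reference solution's totals (pure-time greedy).

    Each total is replaced by 1 when zero so the normalized objective stays
    defined (e.g. an all-paved, all-Good fleet has zero total risk).
    """
    t = sum(r.metrics.transit_hours for r in reference.routes)
    k = sum(r.metrics.risk for r in reference.routes)
    return Normalizers(time_norm=t if t > 0 else 1.0,
                       risk_norm=k if k > 0 else 1.0)


def weighted_objective(solution: "Solution", weights: ObjectiveWeights,
                       norms: Normalizers) -> float:
    """W_t x (total transit / time_norm) + W_p x (total risk / risk_norm)."""
    t = sum(r.metrics.transit_hours for r in solution.routes)
    k = sum(r.metrics.risk for r in solution.routes)
    return weights.weight_time * t / norms.time_norm + \
        weights.weight_risk * k / norms.risk_norm
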