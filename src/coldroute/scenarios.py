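"""Synthetic instance generation and emergency-scenario transforms.

The generator produces deterministic, seeded instances: facilities placed
uniformly on a square, road distances as Euclidean beelines inflated by a
road-wiggle factor (1.3), road-condition classes drawn from a mix over
the four passable classes, and a configurable chance that a pair is not
accessible at all (resampled until the depot stays reachable from every
facility).  Demands are Poisson per (facility, product); the catalogue
always contains at least one cold-chain and one ambient product.

Emergency transforms replicate the operational workflow after a natural
disaster: relocate the distribution warehouse, zero out demand at
facilities that cannot receive stock, scale demand up where patients are
redirected, and mark washed-out roads as not accessible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .instance import (
    NOT_ACCESSIBLE,
    PASSABLE_CLASSES,
    Facility,
    Instance,
    Parameters,
    Product,
    RoadNetwork,
    Vehicle,
)

__all__ = [
    "GeneratorSpec",
    "ScenarioSpec",
    "generate_instance",
    "apply_emergency",
    "example_instance",
    "cyclone_scenario",
]

ROAD_WIGGLE = 1.3  # beeline-to-road distance inflation


@dataclass(frozen=True)
class GeneratorSpec:
    """Knobs for the synthetic instance generator.

    Defaults describe a district-scale distribution: up to a dozen
    facilities within an ~60 km square, a 12-hour delivery window, a
    couple of hundred units of each product per facility, and a road mix
    dominated by partially paved and good dirt roads.
    """

    seed: int = 0
    n_facilities: int = 8  # delivery facilities, excluding the depot
    n_vehicles: int = 2
    area_km: float = 60.0
    demand_intensity: float = 150.0  # mean units per product per facility
    road_class_mix: tuple[float, float, float, float] = (0.25, 0.35, 0.25, 0.15)
    block_probability: float = 0.05
    weight_time: int = 5

    def __post_init__(self):
        if not (1 <= self.n_facilities <= 50):
            raise ValueError("n_facilities must be 1..50")
        if not (1 <= self.n_vehicles <= 5):
            raise ValueError("n_vehicles must be 1..5")
        if abs(sum(self.road_class_mix) - 1.0) > 1e-9:
            raise ValueError("road_class_mix must sum to 1")
        if not (0.0 <= self.block_probability < 1.0):
            raise ValueError("block_probability must be in [0, 1)")


_PRODUCTS = (
    Product("Vaccine (10-dose vial)", requires_cold=True, unit_volume=0.05),
    Product("Diluent & droppers", requires_cold=True, unit_volume=0.03),
    Product("Syringes (box)", requires_cold=False, unit_volume=0.4),
    Product("Essential medicines kit", requires_cold=False, unit_volume=0.25),
)


def generate_instance(spec: GeneratorSpec) -> Instance:
    """Generate a deterministic, solvable synthetic instance."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_facilities
    names = ["Depot"] + [f"Center {i:02d}" for i in range(1, n + 1)]

    xy = rng.uniform(0.0, spec.area_km, size=(n + 1, 2))
    distance: dict[tuple[str, str], float] = {}
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            d = float(np.hypot(*(xy[i] - xy[j]))) * ROAD_WIGGLE
            distance[(names[i], names[j])] = round(max(d, 1.0), 1)

    for _attempt in range(200):
        road: dict[tuple[str, str], str] = {}
        for i in range(n + 1):
            for j in range(i + 1, n + 1):
                if rng.random() < spec.block_probability:
                    cls = NOT_ACCESSIBLE
                else:
                    cls = PASSABLE_CLASSES[
                        int(rng.choice(4, p=spec.road_class_mix))]
                road[(names[i], names[j])] = cls
        if _connected(names, road):
            break
    else:  # pragma: no cover - p(block) < 1 makes this astronomically rare
        road = {k: PASSABLE_CLASSES[1] for k in road}

    products = list(_PRODUCTS)
    demand: dict[tuple[str, str], int] = {}
    for fac in names:
        for p in products:
            if fac == names[0]:
                demand[(fac, p.name)] = 0
            else:
                demand[(fac, p.name)] = int(rng.poisson(spec.demand_intensity))

    facilities = []
    for fac in names:
        cold = float(rng.uniform(20, 60))
        ambient = float(rng.uniform(100, 300))
        if fac == names[0]:  # warehouse: ample storage
            cold, ambient = 5000.0, 20000.0
        facilities.append(Facility(fac, round(cold, 1), round(ambient, 1)))

    conditions = ("Good", "Fair", "Poor")
    vehicles = []
    for k in range(1, spec.n_vehicles + 1):
        vehicles.append(Vehicle(
            name=f"Vehicle {k}",
            available=True,
            condition=conditions[int(rng.choice(3, p=(0.5, 0.3, 0.2)))],
            cold_capacity=round(float(rng.uniform(80, 200)), 1),
            ambient_capacity=round(float(rng.uniform(600, 1500)), 1),
            fuel_consumption=round(float(rng.uniform(0.08, 0.25)), 3),
            crew_size=2,
        ))

    parameters = Parameters(
        depot_name=names[0],
        start_time="07:00",
        return_time="19:00",
        weight_time=spec.weight_time,
        fuel_price=1.5,
        per_diem_rate=15.0,
    )
    return Instance(parameters=parameters, products=products,
                    facilities=facilities, demand=demand, vehicles=vehicles,
                    network=RoadNetwork(distance=distance, road_class=road))


def _connected(names: list[str], road: dict) -> bool:
    adj = {n: [] for n in names}
    for (a, b), cls in road.items():
        if cls != NOT_ACCESSIBLE:
            adj[a].append(b)
            adj[b].append(a)
    seen = {names[0]}
    stack = [names[0]]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(names)


# ---------------------------------------------------------------------------
# Emergency transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """An emergency re-planning scenario applied on top of an instance."""

    new_depot: str | None = None
    zero_demand: tuple[str, ...] = ()
    demand_multipliers: dict[str, float] = field(default_factory=dict)
    road_blocks: tuple[tuple[str, str], ...] = ()

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioSpec":
        return cls(
            new_depot=data.get("new_depot"),
            zero_demand=tuple(data.get("zero_demand", ())),
            demand_multipliers=dict(data.get("demand_multipliers", {})),
            road_blocks=tuple(tuple(p) for p in data.get("road_blocks", ())),
        )

    @classmethod
    def from_file(cls, path) -> "ScenarioSpec":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def fingerprint(self) -> str:
        return repr((self.new_depot, tuple(sorted(self.zero_demand)),
                     tuple(sorted(self.demand_multipliers.items())),
                     tuple(sorted(tuple(sorted(p)) for p in self.road_blocks))))


def apply_emergency(instance: Instance, scenario: ScenarioSpec) -> Instance:
    """Return a new instance with the scenario applied; the input is untouched.

    Raises ``KeyError`` when the scenario references an undeclared
    facility.  Idempotent: re-applying a scenario the instance has already
    absorbed returns an unchanged copy (demand multipliers would otherwise
    compound); distinct scenarios compose.
    """
    names = set(instance.facility_names())
    referenced = set(scenario.zero_demand) | set(scenario.demand_multipliers)
    if scenario.new_depot:
        referenced.add(scenario.new_depot)
    for a, b in scenario.road_blocks:
        referenced.update((a, b))
    unknown = sorted(referenced - names)
    if unknown:
        raise KeyError(f"scenario references undeclared facilities: {unknown}")

    applied = set(getattr(instance, "_applied_scenarios", ()))
    out = instance.copy()
    fp = scenario.fingerprint()
    if fp in applied:
        out._applied_scenarios = applied  # type: ignore[attr-defined]
        return out
    out._applied_scenarios = applied | {fp}  # type: ignore[attr-defined]
    if scenario.new_depot:
        out.parameters = replace(out.parameters, depot_name=scenario.new_depot)
    for (fac, prod), qty in list(out.demand.items()):
        if fac in scenario.zero_demand:
            out.demand[(fac, prod)] = 0
        elif fac in scenario.demand_multipliers and qty:
            out.demand[(fac, prod)] = int(
                math.ceil(qty * scenario.demand_multipliers[fac]))
    for a, b in scenario.road_blocks:
        for key in ((a, b), (b, a)):
            if key in out.network.road_class:
                out.network.road_class[key] = NOT_ACCESSIBLE
        if (a, b) not in out.network.road_class and \
                (b, a) not in out.network.road_class:
            out.network.road_class[(a, b)] = NOT_ACCESSIBLE
    return out


# ---------------------------------------------------------------------------
# Bundled worked example
# ---------------------------------------------------------------------------

def example_instance() -> Instance:
    """A hand-written 7-facility province instance used in docs and tests.

    Province A is the routine distribution warehouse serving Centers B-G;
    two vehicles are available.  All quantities are synthetic.
    """
    names = ["Province A", "Center B", "Center C", "Center D", "Center E",
             "Center F", "Center G"]
    products = [
        Product("Vaccine (10-dose vial)", requires_cold=True, unit_volume=0.05),
        Product("Syringes (box)", requires_cold=False, unit_volume=0.4),
        Product("Essential medicines kit", requires_cold=False, unit_volume=0.25),
    ]
    facilities = [
        Facility("Province A", 4000.0, 15000.0),
        Facility("Center B", 60.0, 400.0),
        Facility("Center C", 25.0, 150.0),
        Facility("Center D", 30.0, 200.0),
        Facility("Center E", 20.0, 120.0),
        Facility("Center F", 40.0, 250.0),
        Facility("Center G", 25.0, 160.0),
    ]
    base_demand = {
        "Province A": (0, 0, 0),
        "Center B": (300, 30, 40),
        "Center C": (150, 15, 20),
        "Center D": (180, 18, 25),
        "Center E": (120, 12, 15),
        "Center F": (250, 25, 30),
        "Center G": (140, 14, 18),
    }
    demand = {}
    for fac, quantities in base_demand.items():
        for p, q in zip(products, quantities):
            demand[(fac, p.name)] = q
    vehicles = [
        Vehicle("Landcruiser_3PL", True, "Good", 32.0, 400.0, 0.14, 2),
        Vehicle("New Vehicle", True, "Fair", 25.0, 300.0, 0.11, 2),
    ]
    # symmetric km matrix (upper triangle), road-wiggled planar layout
    d = {
        ("Province A", "Center B"): 42.0, ("Province A", "Center C"): 28.0,
        ("Province A", "Center D"): 55.0, ("Province A", "Center E"): 74.0,
        ("Province A", "Center F"): 39.0, ("Province A", "Center G"): 61.0,
        ("Center B", "Center C"): 33.0, ("Center B", "Center D"): 47.0,
        ("Center B", "Center E"): 36.0, ("Center B", "Center F"): 25.0,
        ("Center B", "Center G"): 52.0, ("Center C", "Center D"): 30.0,
        ("Center C", "Center E"): 58.0, ("Center C", "Center F"): 44.0,
        ("Center C", "Center G"): 49.0, ("Center D", "Center E"): 38.0,
        ("Center D", "Center F"): 57.0, ("Center D", "Center G"): 24.0,
        ("Center E", "Center F"): 29.0, ("Center E", "Center G"): 31.0,
        ("Center F", "Center G"): 46.0,
    }
    r = {
        ("Province A", "Center B"): "Fully paved",
        ("Province A", "Center C"): "Partially paved",
        ("Province A", "Center D"): "Partially paved",
        ("Province A", "Center E"): "Dirt road (Good Quality)",
        ("Province A", "Center F"): "Fully paved",
        ("Province A", "Center G"): "Dirt road (Good Quality)",
        ("Center B", "Center C"): "Partially paved",
        ("Center B", "Center D"): "Dirt road (Good Quality)",
        ("Center B", "Center E"): "Partially paved",
        ("Center B", "Center F"): "Fully paved",
        ("Center B", "Center G"): "Dirt road (Rough)",
        ("Center C", "Center D"): "Partially paved",
        ("Center C", "Center E"): "Dirt road (Rough)",
        ("Center C", "Center F"): "Partially paved",
        ("Center C", "Center G"): "Dirt road (Good Quality)",
        ("Center D", "Center E"): "Dirt road (Good Quality)",
        ("Center D", "Center F"): "Dirt road (Rough)",
        ("Center D", "Center G"): "Partially paved",
        ("Center E", "Center F"): "Partially paved",
        ("Center E", "Center G"): "Dirt road (Good Quality)",
        ("Center F", "Center G"): "Dirt road (Rough)",
    }
    parameters = Parameters(depot_name="Province A", start_time="08:00",
                            return_time="18:00", weight_time=5,
                            fuel_price=1.5, per_diem_rate=15.0)
    return Instance(parameters=parameters, products=products,
                    facilities=facilities, demand=demand, vehicles=vehicles,
                    network=RoadNetwork(distance=d, road_class=r))


def cyclone_scenario() -> ScenarioSpec:
    """The cyclone emergency applied to :func:`example_instance`.

    The provincial warehouse is damaged, so distribution moves to Center
    B; Province A, Center C and Center D cannot store products and are
    dropped; demand surges at Center B and Center F; the road between
    Center B and Center E is washed out.
    """
    return ScenarioSpec(
        new_depot="Center B",
        zero_demand=("Province A", "Center C", "Center D"),
        demand_multipliers={"Center B": 1.5, "Center F": 1.4},
        road_blocks=(("Center B", "Center E"),),
    )
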