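"""Domain model for single-day cold-chain distribution instances.

A problem instance bundles the planning parameters (depot, daily time
window, objective weight), the product catalogue split into cold-chain and
ambient items, the facility list with storage capacities, the demand table,
the vehicle fleet, and a road network given as a symmetric distance matrix
paired with a road-condition class matrix.

Validation is *total*: :func:`validate_instance` never raises on malformed
but parseable input; it returns a report of blocking errors and
non-blocking warnings, each carrying a sheet/cell location.  Storage
capacity overruns at a facility are warnings only — distribution may still
be planned even when a facility will have to improvise storage.

Units: volumes in liters, distances in km, internal time in decimal hours,
clock I/O in 24-h ``HH:MM``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ROAD_CLASSES",
    "PASSABLE_CLASSES",
    "NOT_ACCESSIBLE",
    "VEHICLE_CONDITIONS",
    "Parameters",
    "Product",
    "Facility",
    "Vehicle",
    "RoadNetwork",
    "Instance",
    "AggregatedLoad",
    "ValidationReport",
    "ValidationMessage",
    "parse_clock",
    "format_clock",
    "validate_instance",
    "aggregate_demand",
    "visit_set",
    "accessible_legs",
]

# Controlled vocabularies.  Road classes mirror the five dropdown values of
# the input sheet; vehicle condition uses the same three-level granularity.
NOT_ACCESSIBLE = "Not accessible"
PASSABLE_CLASSES = (
    "Fully paved",
    "Partially paved",
    "Dirt road (Good Quality)",
    "Dirt road (Rough)",
)
ROAD_CLASSES = PASSABLE_CLASSES + (NOT_ACCESSIBLE,)
VEHICLE_CONDITIONS = ("Good", "Fair", "Poor")

MAX_WINDOW_HOURS = 24.0


def parse_clock(value: str | float | int) -> float:
    """Parse a 24-h ``HH:MM`` clock string (or decimal hours) to hours.

    Accepts ``datetime.time`` as produced by spreadsheet readers.
    ``24:00`` is allowed as the end of the day.
    """
    import datetime

    if isinstance(value, datetime.time):
        return value.hour + value.minute / 60.0 + value.second / 3600.0
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if not 0.0 <= float(value) <= 24.0:
            raise ValueError(f"clock value out of range: {value!r}")
        return float(value)
    text = str(value).strip()
    parts = text.split(":")
    if len(parts) not in (2, 3) or not all(p.isdigit() for p in parts):
        raise ValueError(f"not a HH:MM clock time: {value!r}")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    if h == 24 and m == 0 and s == 0:
        return 24.0
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
        raise ValueError(f"not a valid 24-h clock time: {value!r}")
    return h + m / 60.0 + s / 3600.0


def format_clock(hours: float) -> str:
    """Format decimal hours as ``HH:MM``, rounding half-up to the minute."""
    total_minutes = math.floor(hours * 60.0 + 0.5)
    h, m = divmod(int(total_minutes), 60)
    return f"{h:02d}:{m:02d}"


@dataclass(frozen=True)
class Parameters:
    """Planning parameters shared by every route of the day.

    ``weight_time`` is the user-entered integer weight for transit time,
    0–10; the risk weight is always derived as ``10 - weight_time`` and is
    never entered directly.
    """

    depot_name: str
    start_time: str = "08:00"
    return_time: str = "17:00"
    weight_time: int = 5
    time_budget_seconds: float = 120.0
    service_hours_per_stop: float = 0.0
    fuel_price: float = 1.0
    per_diem_rate: float = 0.0

    @property
    def start_hours(self) -> float:
        return parse_clock(self.start_time)

    @property
    def return_hours(self) -> float:
        return parse_clock(self.return_time)

    @property
    def window_hours(self) -> float:
        """Length of the daily delivery window in hours."""
        return self.return_hours - self.start_hours


@dataclass(frozen=True)
class Product:
    name: str
    requires_cold: bool
    unit_volume: float  # liters per unit


@dataclass(frozen=True)
class Facility:
    name: str
    cold_capacity: float = 0.0  # liters
    ambient_capacity: float = 0.0  # liters


@dataclass(frozen=True)
class Vehicle:
    name: str
    available: bool = True
    condition: str = "Good"
    cold_capacity: float = 0.0  # liters
    ambient_capacity: float = 0.0  # liters
    fuel_consumption: float = 0.1  # liters per km
    crew_size: int = 2


@dataclass
class RoadNetwork:
    """Symmetric distance matrix paired with a road-condition class matrix.

    Cells may hold ``None`` for blanks left in the input sheets; blanks are
    reported as blocking errors by :func:`validate_instance`.
    """

    distance: dict[tuple[str, str], float | None]
    road_class: dict[tuple[str, str], str | None]

    def get_distance(self, i: str, j: str) -> float:
        if i == j:
            return 0.0
        d = self.distance.get((i, j), self.distance.get((j, i)))
        if d is None:
            raise KeyError(f"no distance for leg {i!r} -> {j!r}")
        return d

    def get_class(self, i: str, j: str) -> str:
        if i == j:
            return PASSABLE_CLASSES[0]
        c = self.road_class.get((i, j), self.road_class.get((j, i)))
        if c is None:
            raise KeyError(f"no road class for leg {i!r} -> {j!r}")
        return c

    def is_accessible(self, i: str, j: str) -> bool:
        try:
            return self.get_class(i, j) != NOT_ACCESSIBLE
        except KeyError:
            return False


@dataclass
class Instance:
    """A complete single-day distribution problem."""

    parameters: Parameters
    products: list[Product]
    facilities: list[Facility]
    demand: dict[tuple[str, str], int | None]  # (facility, product) -> units
    vehicles: list[Vehicle]
    network: RoadNetwork

    def facility_names(self) -> list[str]:
        return [f.name for f in self.facilities]

    def product_names(self) -> list[str]:
        return [p.name for p in self.products]

    def product(self, name: str) -> Product:
        for p in self.products:
            if p.name == name:
                return p
        raise KeyError(f"unknown product: {name!r}")

    def facility(self, name: str) -> Facility:
        for f in self.facilities:
            if f.name == name:
                return f
        raise KeyError(f"unknown facility: {name!r}")

    def available_vehicles(self) -> list[Vehicle]:
        return [v for v in self.vehicles if v.available]

    def copy(self) -> "Instance":
        return Instance(
            parameters=replace(self.parameters),
            products=list(self.products),
            facilities=list(self.facilities),
            demand=dict(self.demand),
            vehicles=list(self.vehicles),
            network=RoadNetwork(
                distance=dict(self.network.distance),
                road_class=dict(self.network.road_class),
            ),
        )


@dataclass(frozen=True)
class AggregatedLoad:
    """Demand volume aggregated into the two optimization categories."""

    cold_volume: float = 0.0  # liters
    ambient_volume: float = 0.0  # liters

    def __add__(self, other: "AggregatedLoad") -> "AggregatedLoad":
        return AggregatedLoad(
            self.cold_volume + other.cold_volume,
            self.ambient_volume + other.ambient_volume,
        )


@dataclass(frozen=True)
class ValidationMessage:
    code: str
    location: str  # "sheet!cell-ish" locator
    message: str


@dataclass
class ValidationReport:
    errors: list[ValidationMessage] = field(default_factory=list)
    warnings: list[ValidationMessage] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, code: str, location: str, message: str) -> None:
        self.errors.append(ValidationMessage(code, location, message))

    def warn(self, code: str, location: str, message: str) -> None:
        self.warnings.append(ValidationMessage(code, location, message))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def aggregate_demand(instance: Instance, facility: str) -> AggregatedLoad:
    """Aggregate a facility's demand into cold and ambient liters.

    The optimizer never sees individual products: demand is collapsed into
    the two temperature categories, which is what keeps solve time
    independent of catalogue size.  Raises ``KeyError`` for an undeclared
    facility.
    """
    if facility not in instance.facility_names():
        raise KeyError(f"unknown facility: {facility!r}")
    cold = 0.0
    ambient = 0.0
    for product in instance.products:
        qty = instance.demand.get((facility, product.name)) or 0
        vol = qty * product.unit_volume
        if product.requires_cold:
            cold += vol
        else:
            ambient += vol
    return AggregatedLoad(cold, ambient)


def visit_set(instance: Instance) -> set[str]:
    """Facilities that must be visited: non-depot, positive demand volume.

    Zero-demand facilities are dropped from routing entirely — this is the
    lever emergency planning uses to exclude damaged facilities.  The depot
    is always excluded: it is the origin and terminus of every route.
    """
    depot = instance.parameters.depot_name
    out: set[str] = set()
    for f in instance.facilities:
        if f.name == depot:
            continue
        load = aggregate_demand(instance, f.name)
        if load.cold_volume > 0 or load.ambient_volume > 0:
            out.add(f.name)
    return out


def accessible_legs(instance: Instance) -> set[frozenset[str]]:
    """Unordered facility pairs a route leg may use.

    A pair is excluded when its road class is "Not accessible" (or blank).
    """
    names = instance.facility_names()
    out: set[frozenset[str]] = set()
    for a_idx, a in enumerate(names):
        for b in names[a_idx + 1:]:
            cls = instance.network.road_class.get(
                (a, b), instance.network.road_class.get((b, a))
            )
            if cls is not None and cls != NOT_ACCESSIBLE:
                out.add(frozenset((a, b)))
    return out


def validate_instance(instance: Instance) -> ValidationReport:
    """Check an instance for blocking errors and advisory warnings.

    Never raises: every issue is collected into the report with a
    sheet/cell location.  Errors block solving (blank matrix cells, unknown
    names, out-of-range weight, invalid window, vocabulary violations, no
    available vehicle); facility storage overruns are warnings only.
    """
    report = ValidationReport()
    p = instance.parameters
    names = instance.facility_names()
    name_set = set(names)
    product_names = set(instance.product_names())

    # --- parameters sheet ---
    if len(name_set) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        report.error("DUPLICATE_NAME", "center_capacities!name",
                     f"duplicate facility names: {dupes}")
    prods = instance.product_names()
    if len(product_names) != len(prods):
        dupes = sorted({n for n in prods if prods.count(n) > 1})
        report.error("DUPLICATE_NAME", "products!name",
                     f"duplicate product names: {dupes}")
    if p.depot_name not in name_set:
        report.error("UNKNOWN_NAME", "parameters!depot",
                     f"depot {p.depot_name!r} is not a declared facility")
    if not (isinstance(p.weight_time, int) and 0 <= p.weight_time <= 10):
        report.error("WEIGHT_OUT_OF_RANGE", "parameters!weight_time",
                     f"weight_time must be an integer in 0..10, got {p.weight_time!r}")
    try:
        start, ret = p.start_hours, p.return_hours
    except ValueError as exc:
        report.error("CLOCK_INVALID", "parameters!start_time/return_time", str(exc))
    else:
        if ret <= start:
            report.error("WINDOW_INVALID", "parameters!return_time",
                         f"return time {p.return_time} must be after start {p.start_time}")
        elif ret - start > MAX_WINDOW_HOURS:
            report.error("WINDOW_INVALID", "parameters!return_time",
                         "daily window exceeds 24 hours")
    if p.time_budget_seconds <= 0:
        report.error("BUDGET_INVALID", "parameters!time_budget_seconds",
                     "time budget must be positive")
    if p.service_hours_per_stop < 0:
        report.error("NEGATIVE_VALUE", "parameters!service_hours_per_stop",
                     "service time must be >= 0")

    # --- products sheet ---
    for prod in instance.products:
        if prod.unit_volume <= 0:
            report.error("NEGATIVE_VALUE", f"products!{prod.name}",
                         "unit volume must be > 0")

    # --- vehicle sheet ---
    for v in instance.vehicles:
        if v.condition not in VEHICLE_CONDITIONS:
            report.error("VOCAB_ERROR", f"vehicle!{v.name}",
                         f"condition {v.condition!r} not in {VEHICLE_CONDITIONS}")
        if v.cold_capacity < 0 or v.ambient_capacity < 0:
            report.error("NEGATIVE_VALUE", f"vehicle!{v.name}",
                         "capacities must be >= 0")
        if v.fuel_consumption <= 0:
            report.error("NEGATIVE_VALUE", f"vehicle!{v.name}",
                         "fuel consumption must be > 0")
        if v.crew_size < 1:
            report.error("NEGATIVE_VALUE", f"vehicle!{v.name}",
                         "crew size must be >= 1")
    if not any(v.available for v in instance.vehicles):
        report.error("NO_VEHICLE", "vehicle!available",
                     "no vehicle is marked available")

    # --- demand sheet: blanks are errors, unknown names are errors ---
    for (fac, prod), qty in sorted(instance.demand.items()):
        loc = f"demand!{fac}/{prod}"
        if fac not in name_set:
            report.error("UNKNOWN_NAME", loc, f"facility {fac!r} not declared")
        if prod not in product_names:
            report.error("UNKNOWN_NAME", loc, f"product {prod!r} not declared")
        if qty is None:
            report.error("BLANK_CELL", loc,
                         "demand cell is blank; enter 0 for no demand")
        elif qty < 0 or qty != int(qty):
            report.error("NEGATIVE_VALUE", loc,
                         f"demand must be a non-negative integer, got {qty!r}")
    for fac in names:
        for prod in prods:
            if (fac, prod) not in instance.demand:
                report.error("BLANK_CELL", f"demand!{fac}/{prod}",
                             "demand cell missing; enter 0 for no demand")

    # --- matrices: no blanks, known names, symmetry, valid vocabulary ---
    _check_matrix(report, "distance_data", instance.network.distance,
                  name_set, names, numeric=True)
    _check_matrix(report, "road_condition", instance.network.road_class,
                  name_set, names, numeric=False)

    # --- storage-capacity warnings (never errors) ---
    for fac in instance.facilities:
        load = aggregate_demand(_zero_blanks(instance), fac.name)
        if load.cold_volume > fac.cold_capacity:
            report.warn("STORAGE_EXCEEDED", f"center_capacities!{fac.name}",
                        f"cold demand {load.cold_volume:.1f} L exceeds cold "
                        f"storage capacity {fac.cold_capacity:.1f} L")
        if load.ambient_volume > fac.ambient_capacity:
            report.warn("STORAGE_EXCEEDED", f"center_capacities!{fac.name}",
                        f"ambient demand {load.ambient_volume:.1f} L exceeds "
                        f"ambient storage capacity {fac.ambient_capacity:.1f} L")
    return report


def _zero_blanks(instance: Instance) -> Instance:
    # aggregate_demand treats None as 0 already; kept for clarity
    return instance


def _check_matrix(report, sheet, cells, name_set, names, numeric):
    known = {}
    for (a, b), value in sorted(cells.items(), key=lambda kv: kv[0]):
        loc = f"{sheet}!{a}/{b}"
        if a not in name_set or b not in name_set:
            report.error("UNKNOWN_NAME", loc,
                         f"matrix references undeclared facility in ({a!r}, {b!r})")
            continue
        if value is None:
            report.error("BLANK_CELL", loc,
                         "matrix cell is blank; every cell must be filled")
            continue
        if numeric:
            if not isinstance(value, (int, float)) or value < 0:
                report.error("NEGATIVE_VALUE", loc,
                             f"distance must be a number >= 0, got {value!r}")
                continue
            if a == b and value != 0:
                report.error("DIAGONAL_NONZERO", loc,
                             "distance of a facility to itself must be 0")
        else:
            if value not in ROAD_CLASSES:
                report.error("VOCAB_ERROR", loc,
                             f"road class {value!r} not in {list(ROAD_CLASSES)}")
                continue
        key = frozenset((a, b))
        if a != b:
            if key in known and known[key] != value:
                report.error("ASYMMETRIC", loc,
                             f"matrix is not symmetric at ({a!r}, {b!r}): "
                             f"{known[key]!r} vs {value!r}")
            known[key] = value
    # missing pairs
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if (a, b) not in cells and (b, a) not in cells:
                report.error("BLANK_CELL", f"{sheet}!{a}/{b}",
                             "matrix cell missing; every cell must be filled")
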