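"""Read the seven-sheet input workbook; write the two-sheet output workbook.

Input sheets (case-insensitive names): ``parameters``, ``products``,
``center_capacities``, ``demand``, ``vehicle``, ``distance_data``,
``road_condition``.  Facility names are declared once, in
``center_capacities``, and every other sheet is resolved against that
declaration; likewise product names come only from ``products``.

Two dialects are supported: XLSX (canonical) and a CSV bundle — a
directory holding one ``<sheet>.csv`` per sheet (RFC 4180, UTF-8, header
row) — which is convenient for headless pipelines and version control.

The output workbook has a ``Routes`` sheet (one row per departure event
per route, with utilization and costs) and a ``Health products`` sheet
disaggregating the two optimization categories back into named product
quantities per facility and route.
"""

from __future__ import annotations

import csv
import datetime
import os
from pathlib import Path

from .instance import (
    ROAD_CLASSES,
    VEHICLE_CONDITIONS,
    Facility,
    Instance,
    Parameters,
    Product,
    RoadNetwork,
    Vehicle,
    format_clock,
    parse_clock,
)
from .solver import Solution

__all__ = [
    "SHEET_NAMES",
    "WorkbookError",
    "SchemaError",
    "VocabError",
    "NameResolutionError",
    "read_instance",
    "write_instance",
    "write_solution",
]

SHEET_NAMES = (
    "parameters",
    "products",
    "center_capacities",
    "demand",
    "vehicle",
    "distance_data",
    "road_condition",
)

PARAMETER_KEYS = (
    "depot", "start_time", "return_time", "weight_time",
    "time_budget_seconds", "service_hours_per_stop", "fuel_price",
    "per_diem_rate",
)

# fixed timestamp so identical solutions produce byte-identical workbooks
_FIXED_STAMP = datetime.datetime(2000, 1, 1)


class WorkbookError(ValueError):
    def __init__(self, code: str, location: str, message: str):
        self.code = code
        self.location = location
        super().__init__(f"{code} at {location}: {message}")


class SchemaError(WorkbookError):
    def __init__(self, location, message):
        super().__init__("SCHEMA_ERROR", location, message)


class VocabError(WorkbookError):
    def __init__(self, location, message):
        super().__init__("VOCAB_ERROR", location, message)


class NameResolutionError(WorkbookError):
    def __init__(self, location, message):
        super().__init__("NAME_ERROR", location, message)


# ---------------------------------------------------------------------------
# Raw sheet access (list-of-rows tables, dialect-agnostic)
# ---------------------------------------------------------------------------

def _load_tables(path: str | Path, dialect: str | None) -> dict[str, list[list]]:
    path = Path(path)
    if dialect is None:
        dialect = "csv-bundle" if path.is_dir() else "xlsx"
    if dialect == "xlsx":
        import openpyxl

        wb = openpyxl.load_workbook(path, data_only=True)
        tables = {}
        for ws in wb.worksheets:
            rows = [list(r) for r in ws.iter_rows(values_only=True)]
            tables[ws.title.strip().lower()] = rows
        return tables
    if dialect == "csv-bundle":
        tables = {}
        for f in sorted(path.glob("*.csv")):
            with open(f, newline="", encoding="utf-8") as fh:
                rows = [[_csv_cell(c) for c in row] for row in csv.reader(fh)]
            tables[f.stem.strip().lower()] = rows
        return tables
    raise ValueError(f"unknown dialect {dialect!r}")


def _csv_cell(text: str):
    text = text.strip()
    if text == "":
        return None
    try:
        i = int(text)
        return i
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, str) and not v.strip())


def _as_str(v) -> str:
    return str(v).strip()


def _as_float(v, location) -> float:
    if isinstance(v, (int, float)) and not isinstance(v, bool):
        return float(v)
    try:
        return float(str(v).strip())
    except ValueError:
        raise SchemaError(location, f"expected a number, got {v!r}")


def _as_int(v, location) -> int:
    f = _as_float(v, location)
    if f != int(f):
        raise SchemaError(location, f"expected an integer, got {v!r}")
    return int(f)


def _yes_no(v, location) -> bool:
    s = _as_str(v).lower()
    if s in ("yes", "y"):
        return True
    if s in ("no", "n"):
        return False
    raise VocabError(location, f"expected yes/no, got {v!r}")


def _header_map(rows, sheet, required):
    if not rows:
        raise SchemaError(sheet, "sheet is empty")
    header = [(_as_str(h).lower() if not _is_blank(h) else "") for h in rows[0]]
    cols = {}
    for k, name in enumerate(header):
        if name:
            cols[name] = k
    for req in required:
        if req not in cols:
            raise SchemaError(f"{sheet}!row1", f"missing column {req!r}")
    return cols


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_instance(path: str | Path, dialect: str | None = None) -> Instance:
    """Parse an input workbook (or CSV bundle) into an :class:`Instance`.

    Blank matrix and demand cells are preserved as ``None`` so that
    validation can report their locations; structural problems (missing
    sheets/columns, vocabulary violations, names that do not resolve
    against the declaration sheets) raise :class:`WorkbookError`.
    """
    tables = _load_tables(path, dialect)
    for sheet in SHEET_NAMES:
        if sheet not in tables:
            raise SchemaError(sheet, "required sheet is missing")

    # parameters: key/value pairs
    params: dict[str, object] = {}
    for i, row in enumerate(tables["parameters"]):
        if not row or _is_blank(row[0]):
            continue
        key = _as_str(row[0]).lower()
        if key in ("parameter", "key"):  # header row
            continue
        value = row[1] if len(row) > 1 else None
        params[key] = value
    loc = "parameters"
    missing = [k for k in ("depot", "start_time", "return_time", "weight_time")
               if k not in params or _is_blank(params[k])]
    if missing:
        raise SchemaError(loc, f"missing parameter rows: {missing}")

    def _clock(key):
        v = params[key]
        try:
            return format_clock(parse_clock(v))
        except ValueError as exc:
            raise SchemaError(f"{loc}!{key}", str(exc))

    parameters = Parameters(
        depot_name=_as_str(params["depot"]),
        start_time=_clock("start_time"),
        return_time=_clock("return_time"),
        weight_time=_as_int(params["weight_time"], f"{loc}!weight_time"),
        time_budget_seconds=_as_float(params.get("time_budget_seconds", 120),
                                      f"{loc}!time_budget_seconds"),
        service_hours_per_stop=_as_float(params.get("service_hours_per_stop", 0),
                                         f"{loc}!service_hours_per_stop"),
        fuel_price=_as_float(params.get("fuel_price", 1.0), f"{loc}!fuel_price"),
        per_diem_rate=_as_float(params.get("per_diem_rate", 0.0),
                                f"{loc}!per_diem_rate"),
    )

    # products
    rows = tables["products"]
    cols = _header_map(rows, "products", ("name", "requires_cold", "unit_volume_liters"))
    products = []
    for i, row in enumerate(rows[1:], start=2):
        if not row or _is_blank(row[cols["name"]]):
            continue
        loc = f"products!row{i}"
        products.append(Product(
            name=_as_str(row[cols["name"]]),
            requires_cold=_yes_no(row[cols["requires_cold"]], loc),
            unit_volume=_as_float(row[cols["unit_volume_liters"]], loc),
        ))

    # center_capacities: the single source of facility names
    rows = tables["center_capacities"]
    cols = _header_map(rows, "center_capacities",
                       ("name", "cold_capacity_liters", "ambient_capacity_liters"))
    facilities = []
    for i, row in enumerate(rows[1:], start=2):
        if not row or _is_blank(row[cols["name"]]):
            continue
        loc = f"center_capacities!row{i}"
        facilities.append(Facility(
            name=_as_str(row[cols["name"]]),
            cold_capacity=_as_float(row[cols["cold_capacity_liters"]], loc),
            ambient_capacity=_as_float(row[cols["ambient_capacity_liters"]], loc),
        ))
    facility_names = [f.name for f in facilities]
    product_names = [p.name for p in products]

    if parameters.depot_name not in facility_names:
        raise NameResolutionError(
            "parameters!depot",
            f"depot {parameters.depot_name!r} is not declared in center_capacities")

    # demand: facility rows x product columns
    rows = tables["demand"]
    cols = _header_map(rows, "demand", ("facility",))
    header = rows[0]
    col_products = []
    for k, h in enumerate(header):
        if k == cols["facility"] or _is_blank(h):
            continue
        name = _as_str(h)
        if name not in product_names:
            raise NameResolutionError(f"demand!col{k + 1}",
                                      f"product {name!r} not declared in products")
        col_products.append((k, name))
    demand: dict[tuple[str, str], int | None] = {}
    for i, row in enumerate(rows[1:], start=2):
        if not row or _is_blank(row[cols["facility"]]):
            continue
        fac = _as_str(row[cols["facility"]])
        if fac not in facility_names:
            raise NameResolutionError(
                f"demand!row{i}", f"facility {fac!r} not declared in center_capacities")
        for k, prod in col_products:
            cell = row[k] if k < len(row) else None
            if _is_blank(cell):
                demand[(fac, prod)] = None
            else:
                demand[(fac, prod)] = _as_int(cell, f"demand!row{i}/{prod}")

    # vehicle
    rows = tables["vehicle"]
    cols = _header_map(rows, "vehicle",
                       ("name", "available", "condition", "cold_capacity_liters",
                        "ambient_capacity_liters", "fuel_consumption_l_per_km"))
    vehicles = []
    for i, row in enumerate(rows[1:], start=2):
        if not row or _is_blank(row[cols["name"]]):
            continue
        loc = f"vehicle!row{i}"
        avail_s = _as_str(row[cols["available"]]).lower()
        if avail_s not in ("available", "not available"):
            raise VocabError(loc, f"availability must be 'available' or "
                                  f"'not available', got {row[cols['available']]!r}")
        cond = _as_str(row[cols["condition"]])
        if cond not in VEHICLE_CONDITIONS:
            raise VocabError(loc, f"condition {cond!r} not in {VEHICLE_CONDITIONS}")
        crew = 2
        if "crew_size" in cols and not _is_blank(row[cols["crew_size"]]):
            crew = _as_int(row[cols["crew_size"]], loc)
        vehicles.append(Vehicle(
            name=_as_str(row[cols["name"]]),
            available=avail_s == "available",
            condition=cond,
            cold_capacity=_as_float(row[cols["cold_capacity_liters"]], loc),
            ambient_capacity=_as_float(row[cols["ambient_capacity_liters"]], loc),
            fuel_consumption=_as_float(row[cols["fuel_consumption_l_per_km"]], loc),
            crew_size=crew,
        ))

    distance = _read_matrix(tables["distance_data"], "distance_data",
                            facility_names, numeric=True)
    road = _read_matrix(tables["road_condition"], "road_condition",
                        facility_names, numeric=False)

    return Instance(parameters=parameters, products=products,
                    facilities=facilities, demand=demand, vehicles=vehicles,
                    network=RoadNetwork(distance=distance, road_class=road))


def _read_matrix(rows, sheet, facility_names, numeric):
    if not rows:
        raise SchemaError(sheet, "sheet is empty")
    header = rows[0]
    col_names = []
    for k, h in enumerate(header[1:], start=1):
        if _is_blank(h):
            continue
        name = _as_str(h)
        if name not in facility_names:
            raise NameResolutionError(f"{sheet}!col{k + 1}",
                                      f"facility {name!r} not declared")
        col_names.append((k, name))
    cells: dict[tuple[str, str], object] = {}
    for i, row in enumerate(rows[1:], start=2):
        if not row or _is_blank(row[0]):
            continue
        a = _as_str(row[0])
        if a not in facility_names:
            raise NameResolutionError(f"{sheet}!row{i}", f"facility {a!r} not declared")
        for k, b in col_names:
            cell = row[k] if k < len(row) else None
            loc = f"{sheet}!{a}/{b}"
            if _is_blank(cell):
                value = None
            elif numeric:
                value = _as_float(cell, loc)
            else:
                value = _as_str(cell)
                if value not in ROAD_CLASSES:
                    raise VocabError(loc, f"road class {value!r} not in "
                                          f"{list(ROAD_CLASSES)}")
            prev = cells.get((b, a))
            if a != b and prev is not None and value is not None and prev != value:
                raise SchemaError(loc, f"matrix is not symmetric: {prev!r} vs {value!r}")
            cells[(a, b)] = value
    return cells


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _instance_tables(instance: Instance) -> dict[str, list[list]]:
    p = instance.parameters
    tables: dict[str, list[list]] = {}
    tables["parameters"] = [
        ["parameter", "value"],
        ["depot", p.depot_name],
        ["start_time", p.start_time],
        ["return_time", p.return_time],
        ["weight_time", p.weight_time],
        ["time_budget_seconds", p.time_budget_seconds],
        ["service_hours_per_stop", p.service_hours_per_stop],
        ["fuel_price", p.fuel_price],
        ["per_diem_rate", p.per_diem_rate],
    ]
    tables["products"] = [["name", "requires_cold", "unit_volume_liters"]] + [
        [pr.name, "yes" if pr.requires_cold else "no", pr.unit_volume]
        for pr in instance.products
    ]
    tables["center_capacities"] = [
        ["name", "cold_capacity_liters", "ambient_capacity_liters"]
    ] + [[f.name, f.cold_capacity, f.ambient_capacity] for f in instance.facilities]
    prods = instance.product_names()
    tables["demand"] = [["facility", *prods]] + [
        [f, *[instance.demand.get((f, pr)) for pr in prods]]
        for f in instance.facility_names()
    ]
    tables["vehicle"] = [
        ["name", "available", "condition", "cold_capacity_liters",
         "ambient_capacity_liters", "fuel_consumption_l_per_km", "crew_size"]
    ] + [
        [v.name, "available" if v.available else "not available", v.condition,
         v.cold_capacity, v.ambient_capacity, v.fuel_consumption, v.crew_size]
        for v in instance.vehicles
    ]
    names = instance.facility_names()

    def matrix(cells, diag):
        rows = [["", *names]]
        for a in names:
            row: list = [a]
            for b in names:
                if a == b:
                    row.append(diag)
                else:
                    row.append(cells.get((a, b), cells.get((b, a))))
            rows.append(row)
        return rows

    tables["distance_data"] = matrix(instance.network.distance, 0)
    tables["road_condition"] = matrix(instance.network.road_class, "Fully paved")
    return tables


def _write_tables(tables: dict[str, list[list]], path: str | Path,
                  dialect: str | None, order) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "csv-bundle" if (path.suffix.lower() != ".xlsx") else "xlsx"
    if dialect == "xlsx":
        import openpyxl

        wb = openpyxl.Workbook()
        wb.remove(wb.active)
        for sheet in order:
            ws = wb.create_sheet(sheet)
            for row in tables[sheet]:
                ws.append(row)
        wb.properties.created = _FIXED_STAMP
        wb.properties.modified = _FIXED_STAMP
        wb.save(path)
    elif dialect == "csv-bundle":
        os.makedirs(path, exist_ok=True)
        for sheet in order:
            with open(path / f"{sheet}.csv", "w", newline="",
                      encoding="utf-8") as fh:
                w = csv.writer(fh)
                for row in tables[sheet]:
                    w.writerow(["" if c is None else c for c in row])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_instance(instance: Instance, path: str | Path,
                   dialect: str | None = None) -> None:
    """Write an instance back out as a seven-sheet workbook or CSV bundle."""
    _write_tables(_instance_tables(instance), path, dialect, SHEET_NAMES)


def write_solution(solution: Solution, instance: Instance, path: str | Path,
                   dialect: str | None = None) -> None:
    """Write the two-sheet output workbook for a solution.

    ``Routes`` holds one row per departure event (the depot departure and
    each delivery stop) with the route's capacity utilization per
    temperature class and its fuel and per-diem costs.  ``Health products``
    disaggregates each route's cold/ambient load back into named product
    quantities per facility.
    """
    p = instance.parameters
    vehicles = {v.name: v for v in instance.vehicles}
    routes_rows: list[list] = [[
        "vehicle", "route", "day", "stop", "departure_time",
        "cold_utilization_pct", "ambient_utilization_pct", "distance_km",
        "transit_hours", "risk", "fuel_cost", "per_diem_cost",
    ]]
    products_rows: list[list] = [[
        "facility", "product", "vehicle", "route", "day", "quantity",
    ]]
    for ri, r in enumerate(solution.routes, start=1):
        veh = vehicles[r.vehicle]
        cold_u = (100.0 * r.load.cold_volume / veh.cold_capacity
                  if veh.cold_capacity > 0 else 0.0)
        amb_u = (100.0 * r.load.ambient_volume / veh.ambient_capacity
                 if veh.ambient_capacity > 0 else 0.0)
        common = [round(cold_u, 1), round(amb_u, 1),
                  round(r.metrics.distance_km, 2),
                  round(r.metrics.transit_hours, 3),
                  round(r.metrics.risk, 3),
                  round(r.metrics.fuel_cost, 2),
                  round(r.metrics.per_diem_cost, 2)]
        routes_rows.append([r.vehicle, ri, r.day, p.depot_name, p.start_time,
                            *common])
        for stop, dep in zip(r.stops, r.departure_times):
            routes_rows.append([r.vehicle, ri, r.day, stop, dep, *common])
        for stop in r.stops:
            for prod in instance.products:
                qty = instance.demand.get((stop, prod.name)) or 0
                if qty:
                    products_rows.append([stop, prod.name, r.vehicle, ri,
                                          r.day, qty])
    _write_tables({"Routes": routes_rows, "Health products": products_rows},
                  path, dialect, ("Routes", "Health products"))
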