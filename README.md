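# coldroute

Route planning for last-mile distribution of vaccines and other health
products in low-resource settings. Given one spreadsheet describing a
distribution warehouse, the health facilities it serves, their demand for
cold-chain and ambient products, the vehicle fleet, and a road network
(distances plus road-condition classes), `coldroute` produces feasible
single-day delivery routes that minimize a user-weighted, normalized
combination of **total transit time** and **spoilage risk**, and reports
departure schedules, delivered quantities, and fuel/per-diem costs.

The intended users are logisticians planning routine resupply runs or
re-planning under an emergency (a flood or cyclone that relocates the
warehouse, drops facilities, and washes out roads).

## The model

Facilities with positive demand form the *visit set*; each must be
visited exactly once by one vehicle on a depot-to-depot round trip that
fits the daily delivery window (at most 24 h). Product demand is
aggregated into two temperature categories — cold-chain and ambient
liters — checked against each vehicle's split transport capacity, so the
catalogue size never affects solve time. Available vehicles must be used
evenly: per-vehicle route counts may differ by at most one, with extra
routes of one vehicle running on consecutive days.

Each road pair carries a condition class (`Fully paved`, `Partially
paved`, `Dirt road (Good Quality)`, `Dirt road (Rough)`, `Not
accessible`) that sets travel speed and a per-km risk factor; vehicle
condition (`Good`/`Fair`/`Poor`) adds a per-km risk addend. A leg of
*d* km contributes *d*/speed hours and *d*·(road + vehicle) risk units.
The objective is

```
minimize  W_t · T/T₀  +  W_p · R/R₀ ,     W_p = 10 − W_t
```

where `T` and `R` are the solution's total transit hours and risk,
`T₀`, `R₀` are the totals of a deterministic pure-time greedy reference
(so a 5/5 weighting treats both objectives equally regardless of scale),
and the user enters only the integer time weight `W_t ∈ [0, 10]`.

The solver embeds an indexing rule inside an anytime depth-first
branch-and-bound: a *vehicle index* (fewest routes, then capacity,
condition, name) picks which vehicle opens the next route, and a
*facility index* — the normalized marginal objective of the candidate
leg, behind a hard feasibility filter — picks each next stop,
recalculated after every insertion. Branch-and-bound then improves the
greedy incumbent within a time budget (default 120 s), pruning with an
admissible entering-cost bound; with `branching_width="all"` and enough
budget the returned optimum is certified. For small instances an
independent brute-force enumeration oracle (`coldroute.oracle`) provides
the ground truth used in testing.

## Input and output formats

Input is one XLSX workbook (or, equivalently, a directory of CSV files,
one per sheet) with seven sheets: `parameters` (key/value rows: `depot`,
`start_time`, `return_time`, `weight_time`, `time_budget_seconds`,
`service_hours_per_stop`, `fuel_price`, `per_diem_rate`), `products`
(`name`, `requires_cold` yes/no, `unit_volume_liters`),
`center_capacities` (`name`, `cold_capacity_liters`,
`ambient_capacity_liters` — the *only* place facility names are
declared), `demand` (facility rows × product columns, units),
`vehicle` (`name`, `available`/`not available`, `condition`,
capacities, `fuel_consumption_l_per_km`, `crew_size`), and the two
symmetric facility×facility matrices `distance_data` (km) and
`road_condition` (the five classes above). Blank matrix or demand cells
are blocking errors reported with their location; a facility whose
demand exceeds its storage capacity produces a warning but does not
block solving.

Output is a two-sheet workbook: `Routes` (one row per departure event
with clock times, capacity utilization per temperature class, distance,
transit, risk, and costs) and `Health products` (named product
quantities per facility, vehicle and route — the disaggregation of the
two optimization categories, which re-sums exactly to the input demand).

## Worked example

The bundled example (`coldroute.example_instance()`) is a province
warehouse serving six health centers with a vaccine and two ambient
products, and two vehicles whose cold boxes are too small for a single
tour:

```bash
python -c "import coldroute; coldroute.write_instance(coldroute.example_instance(), 'province.xlsx')"
coldroute solve province.xlsx -o routes.xlsx --width all --time-budget 30
```

prints

```
routes: 3
objective score: 10.0000
total transit: 6.02 h
total risk: 370.0
total distance: 349.0 km
fuel cost: 69.78
per diem cost: 90.00
search completed: yes
```

Three routes are needed because total cold demand (57 L) exceeds any one
vehicle's cold box: the Landcruiser runs two routes on consecutive days
(Center B alone, then C–D–G–E) and the second vehicle takes Center F, so
fleet use stays even (2 vs 1). The score of exactly 10 means the
certified optimum coincides with the normalization reference here. The
`Routes` sheet shows the Landcruiser leaving Province A at 08:00 and
departing Center C at 08:28 with its cold box 92 % full.

The emergency workflow applies a scenario file on top of an instance —
relocate the depot, zero demand at damaged facilities, scale demand up
where patients are redirected, and block washed-out roads:

```bash
coldroute emergency province.xlsx --scenario cyclone.yaml -o emergency.xlsx
coldroute solve emergency.xlsx -o emergency_routes.xlsx
```

Other subcommands: `coldroute validate IN` (exit 0 when only warnings),
`coldroute generate --seed N --facilities K --vehicles V -o OUT` for
synthetic workbooks. Road speeds and risk coefficients can be overridden
with `--profile profile.yaml`.

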