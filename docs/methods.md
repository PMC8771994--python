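# Methods

## Problem statement

A single distribution warehouse (the depot) must deliver health products
to a set of facilities in one day. Products are either cold-chain or
ambient; per-facility demand is aggregated into those two volume
categories, and each vehicle has separate cold and ambient transport
capacities. Roads between facility pairs carry one of four passable
condition classes or are not accessible; vehicles carry a condition
rating. A solution is a set of depot round trips ("routes"), each
assigned to an available vehicle, that together visit every
positive-demand facility exactly once, respect capacities, only use
accessible legs, fit the daily window, and use the fleet evenly
(per-vehicle route counts differ by at most one; a vehicle's second and
later routes run on the following days).

Facilities with zero demand are excluded from routing entirely. This is
deliberate: emergency re-planning drops facilities by zeroing their
demand, and "visited exactly once" applies only to facilities that need
stock.

## Objective and normalization

Two objectives are combined with a single user weight `W_t ∈ {0..10}`
(`W_p = 10 − W_t` is always derived, never entered):

* transit time `T`: sum over legs of distance/speed plus a configurable
  service time per delivery stop;
* risk `R`: sum over legs of distance × (road risk factor + vehicle risk
  addend), a linear proxy for temperature-excursion exposure — longer
  time on worse roads in less reliable vehicles scales risk
  proportionally. A multiplicative combination of the two coefficients
  is available via the profile's `combine: multiply` switch for users
  who prefer interaction effects.

The scalar objective is `W_t·T/T₀ + W_p·R/R₀`. The normalizers `T₀, R₀`
are the totals of the *pure-time greedy* solution (the bootstrap pass of
the construction heuristic), replaced by 1 when zero. Using an
instance-intrinsic, deterministic reference makes scores comparable
across weights on the same instance and gives the identity that the
reference itself always scores exactly 10. If the bootstrap pass cannot
find a feasible solution (rare; see below) the normalizers fall back to
(1, 1), which leaves the optimization well-defined, merely unscaled.

### Default road profile

The condition vocabularies are fixed; the numbers attached to them are
planning defaults, configurable via YAML/JSON:

| road class | speed (km/h) | risk/km |
|---|---|---|
| Fully paved | 80 | 0 |
| Partially paved | 60 | 1 |
| Dirt road (Good Quality) | 40 | 2 |
| Dirt road (Rough) | 25 | 4 |

Vehicle addends: Good 0, Fair 1, Poor 2 per km. Risk is dimensionless;
only ratios matter because of the normalization.

## Solver

**Construction (indexing rule).** Routes are built one at a time. A
*vehicle index* — the lexicographic key (routes already assigned
ascending, total capacity descending, condition Good<Fair<Poor, name) —
decides which vehicle opens the next route; restricting openings to
minimum-count vehicles enforces the evenness constraint incrementally. A
*facility index* — the normalized marginal objective of the leg from the
route's current position to the candidate — picks each next stop and is
recalculated after every insertion. A candidate is filtered out when the
leg is inaccessible, its load overflows remaining capacity, or elapsed
time + leg + service + a lower bound on the accessible return to the
depot would exceed the window. The return bound is a Dijkstra shortest
path (travel plus per-hop service) to the depot on the accessible graph;
it is admissible but not exact, because a real route must return by a
*direct* leg from its final stop and cannot revisit facilities, so the
construction resolves dead ends by dropping the last stop and barring it
from that route. The greedy pass is a heuristic: on rare instances where
a facility can only be served mid-route it gives up even though a
solution exists; the branch-and-bound below still finds it.

**Branch-and-bound.** Depth-first, anytime, seeded with the greedy
incumbent. At each node the search branches on the `branching_width`
best facility-index extensions of the open route plus "close the route"
(closing is a genuine alternative, not a fallback, so route-count
trade-offs are explored). When opening a route in exhaustive mode
(`branching_width="all"`), the search branches over every distinct
capacity/condition signature among minimum-count vehicles — this covers
every evenness-respecting assignment of routes to vehicles — while in
heuristic mode the single best-index vehicle is used, matching the
construction rule. Nodes are pruned when the accumulated normalized cost
plus an admissible bound (for each unvisited facility, the cheapest
accessible entering leg under the best available vehicle condition)
cannot beat the incumbent. The time budget (default 120 s) is checked
every 512 expansions; at expiry the best incumbent is returned and the
solution is marked `search_completed=False`. All tie-breaks are
lexicographic and the solver contains no randomness, so identical inputs
give identical solutions.

With unlimited width and budget the search is exhaustive and the result
is a certified optimum under the hard evenness constraint. Exactness is
verified against an independent brute-force oracle that enumerates every
ordered partition of the visit set into route sequences and every
evenness-respecting vehicle assignment (capped at 8 facilities / 3
vehicles; worst case well under a minute).

### Numerical choices

* Feasibility comparisons use a 1e-9 slack; incumbent improvement
  requires a 1e-12 margin, so equal-score optima keep the first one
  found (deterministic).
* Clock times are printed rounded half-up to the minute; all arithmetic
  is in decimal hours.
* Capacity utilization is reported as the route's initial load over
  vehicle capacity — the maximum over legs, since a delivery route only
  sheds load.
* Per diem is charged once per route (one crew-day), fuel as distance ×
  consumption × price; costs are reported, never optimized.

## Validation

`validate_instance` is total: it returns a report and never raises.
Blocking errors: blank matrix or demand cells (with sheet/cell
location), undeclared names, weight outside 0–10, invalid or >24 h
window, vocabulary violations, matrix asymmetry, no available vehicle.
Storage-capacity overruns at a facility are warnings only — facilities
improvise storage in practice, so the optimization may still run. A
clean report guarantees the instance is well-formed, not that it is
routable: routability depends on window/accessibility interactions that
only the solver can decide, and `solve` raises `InfeasibleInstanceError`
with the reason when no assignment exists.

## Synthetic instances

The generator emulates a district-scale distribution: a depot and up to
50 facilities placed uniformly in a square (default 60 km side), road
distances as Euclidean beelines × 1.3 (a documented beeline-to-road
wiggle factor), road classes drawn from a mix weighted toward partially
paved and good dirt roads, and a small probability (default 0.05) that a
pair is not accessible, resampled until the depot remains reachable from
every facility. Demand is Poisson (default mean 150 units per product
per facility) over a four-product catalogue with two cold and two
ambient items; vehicle capacities are drawn generously enough that any
single facility fits some vehicle. The window default (07:00–19:00)
comfortably admits round trips within the placement area.

What the generator does **not** emulate: real geography and road-network
topology (distances are wiggled beelines, so near-metric), correlated
road damage, demand seasonality, heterogeneous facility sizes, or
stochastic travel times. Passing tests therefore demonstrate algorithmic
correctness under controlled conditions, not predictive accuracy on any
particular country's network.

Road blocks can still make an instance genuinely unroutable (e.g. a
facility whose only accessible neighbors cannot host a round trip);
solver and oracle then agree on infeasibility, and the test batches
treat that agreement as such rather than hiding those instances.

## Emergency transforms

`apply_emergency` composes four operations: depot relocation, demand
zeroing, demand multipliers (rounded up to whole units), and
bidirectional road blocks. The input instance is never modified.
Re-applying a scenario an instance has already absorbed is a no-op
(instances track applied-scenario fingerprints), so the operation is
idempotent while distinct scenarios still compose.

## Design choices that were genuinely open

* **Evenness as a hard constraint.** "As evenly as possible" could be a
  soft objective; the strictest reading (counts differ ≤ 1) is enforced
  in both solver and oracle. The soft alternative would add a penalty
  term and is noted as future work.
* **Second routes run the next day** rather than later the same day;
  each route is independently bounded by the daily window.
* **Fuel consumption lives on the vehicle**, not globally, since fleets
  are heterogeneous.
* **Additive road/vehicle risk** by default, multiplicative available;
  with no measured coefficients either form is a modeling choice, and
  additivity keeps a Good vehicle on a paved road at exactly zero risk.
* **No pass-through travel**: legs exist only between consecutive
  delivery stops, so a blocked direct road cannot be bypassed except by
  reordering deliveries. This makes "never use a blocked road"
  verifiable directly on the route structure.
* **Distance matrix is strictly symmetric** and enforced at read time.

## Problem sizes used in the checks

The test suite and acceptance script certify optimality on batches of
3–6-facility instances against the enumeration oracle (100 instances × 5
weights in the suite, 40 × 5 in the script), fuzz feasibility on 4–12
facility instances (500 / 150), and demonstrate anytime behavior on a
20-facility, 3-vehicle instance with a 30 s budget. The solver's
operating envelope is larger — 50 facilities solve comfortably within
the 120 s default budget — and the envelope check is part of the
interactive examples rather than the routine batches.

## Known limitations

Single-day routes only (no overnight cold-chain storage en route);
demand must be met exactly (no partial deliveries or supply rationing);
facility storage is advisory; travel times are deterministic; the
exhaustive mode is exponential and practical only below ~8 facilities.
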