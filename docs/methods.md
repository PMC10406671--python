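# Methods

## Model and assumptions

`aednet` compares the annual cost of two ways to guarantee that an AED can
reach any point of a region within a response-time budget *d*: a network
of stationary devices fetched on foot, and a network of drone (UAS) bases
that fly the device to the scene.

The coverage geometry is a Christaller comb: the region is tiled by
regular hexagons inscribed in each service point's operational-radius
circle, so every point lies within the radius of exactly one centre. This
assumes Euclidean travel (no road network or terrain), an evenly treated
area (coverage is planned per km², not per inhabitant), and an
average-speed abstraction for the drone (take-off and landing are folded
into a 1-minute access time and a 60 km/h mean speed). These are the
appropriate assumptions for a *planning-level* cost comparison; they are
not a dispatch simulator.

Cost is interval-fixed: unit counts are ceilings of area ratios, so total
cost jumps by one unit cost each time the area forces an extra device.
Airborne counts apply the redundancy multiplier *between* two ceilings —
locations are counted first, then over-provisioned, then rounded up again
— which matters whenever the location count is odd. Variable per-use
costs (electrodes, batteries, charging) are orders of magnitude below the
fixed costs at plausible utilisation and are excluded from network
totals; `UnitCostBreakdown` still models them so unit costs can be built
up from acquisition price, lifetime and consumables by straight-line
depreciation.

The sensitivity analysis solves for indifference unit costs in closed
form. At fixed unit counts, total cost is linear in unit cost, so the
break-even price of mode A against mode B is simply K_B / N_A. No root
finding is involved, and back-substitution reproduces the competing total
exactly (to the 0.005 € rounding of a 2-decimal price).

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| access time a_s, a_m | 1 | min | find/unlock the AED; drone take-off + landing |
| speed b_s | 0.1 | km/min | brisk walk of a lay responder |
| speed b_m | 1.0 | km/min | drone average incl. manoeuvres (60 km/h) |
| response times d | 3…8 | min | must undercut the ~9-min statutory EMS target |
| stationary unit cost k_s | 170 / 263 / 405 | €/yr | cheapest, average, dearest device |
| airborne unit cost k_m | 32 248 / 45 000 / 55 000 | €/yr | base (127 500 € octocopter over 4 yr + AED) and two conservative mark-ups |
| redundancy ρ | 1.5 (airborne) | — | availability buffer for crashes, faults, weather |
| full area | 3930 | km² | reference rural district |
| hot-spot area | 680.4 | km² | aggregate area of OHCA focal points |

Unit costs are treated as opaque annual figures: their published
composition does not decompose cleanly (the base airborne figure is
within ~10 € of acquisition/4 + mid-range AED cost + charging, but the
residual is unexplained), so the printed values are used verbatim.
Response times below 3 minutes trigger a warning (operationally
unrealistic); a response time not exceeding the access time is a hard
error, since the radius would be non-positive.

Internal units are minutes and km/min; a config may give the drone speed
in km/h, converted at load.

## Synthetic OHCA registry

The generator emulates the *structure* of a two-year regional OHCA
registry — 555 events on 3930 km², roughly three quarters of them inside
hot spots — not its geography. Events are a truncated Thomas-type
process: cluster centres uniform over a 78.6 × 50 km rectangle, Gaussian
dispersion around each centre (resampled into the region), plus a uniform
background; timestamps are i.i.d. uniform over 730 days. Hot spots are
1-km² axis-aligned grid cells with ≥ 12 cases, the simplest rule
consistent with a count-threshold definition.

The defaults — 16 clusters, σ = 0.15 km, 10% background — were selected
by the shipped `calibrate_to_study` grid search against the coverage
target 409/555 ≈ 0.737 averaged over 20 seeds, and give a mean covered
fraction of ≈ 0.755 (SD ≈ 0.036) over 50 seeds.

One structural limit is worth stating plainly: with 555 events and a
12-case cell threshold, at most ⌊555/12⌋ = 46 cells can ever be flagged,
so the simulated hot-spot *area* (~18 km² on average) is far below the
680.4 km² of the reference focal points, whose spatial definition
(unstated in the source material) clearly aggregates larger units than
1-km² cells. The package therefore treats 680.4 km² as a fixed input for
all cost computations — the simulation stage feeds the pipeline when a
user wants an end-to-end synthetic run (`aednet full` without
`--hotspot-area`), but no published-number reproduction depends on it.
Passing synthetic tests consequently show that the event→hot-spot→cost
pipeline is correct and calibrated at the event-coverage level; they say
nothing about real incident geography, population weighting, or the true
registry's spatial aggregation.

## Numerical choices

- Unit counts use the exact mathematical ceiling; integer ratios are fixed
  points (6 locations × 1.5 = 9 drones exactly, not 10).
- sin(60°) is evaluated in degrees (√3/2); catchments and costs are kept
  at full precision internally. Currency totals are exact integers
  whenever unit costs are integers.
- Reported prices round half-up to 2 decimals; comparisons and
  back-substitution use unrounded values.
- Grid cells are anchored at the region origin; events on a cell's upper
  boundary are clamped into the last cell so no event is lost.
- Results tables are emitted in a fixed order (area, d ascending, mode,
  unit cost ascending) so CSV output is deterministic and diffable.

## Design choices

- The dominance report (`compare_modes`) enumerates the full 3 × 3 cross
  of unit-cost levels per (area, d) and tags the rank-matched diagonal,
  rather than guessing a single pairing rule; this makes the one
  constellation where the stationary network wins (cheapest stationary vs
  dearest airborne at d = 8) explicit.
- Hot-spot cells are exported as individual square polygons (GeoJSON,
  local planar km, no CRS); adjacent cells are not merged since area is
  additive either way.
- The CLI (`scenarios`, `sensitivity`, `simulate`, `full`, `report`) is a
  thin layer over the library; all logic lives in importable modules.

## Problem sizes

Everything closed-form runs in well under a second (72 scenario cells, 72
indifference points). Stochastic checks use 555-event simulations across
20–50 seeds, a few seconds in total; the Monte-Carlo hexagon oracle uses
10⁵ points and the tiling oracle rectangles up to 120 × 120 km at unit
radius.

## Known limitations

Euclidean geometry ignores roads, water and no-fly zones; the redundancy
factor is a flat multiplier, not a reliability model; no population
weighting, so cost per *covered inhabitant* is out of scope; clinical
outcomes (QALYs/DALYs) are not modelled — response time is the sole
effectiveness proxy; and the temporal dimension of events is structureless
(uniform), so seasonal or diurnal clustering cannot be studied.
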