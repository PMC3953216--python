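# Methods

This note documents the models implemented in `spanflow`, the conventions
chosen where the underlying methodology leaves them open, and what the
synthetic test fixtures do and do not demonstrate.

## Grid model

All spatial data are square-celled rasters with 0-based (row, col)
indexing, row 0 at the north edge, and coordinates anchored at the
lower-left corner. One sentinel value per layer marks nodata; nodata
cells are excluded from every aggregate. The canonical on-disk format is
the ESRI ASCII grid; values are written in the shortest decimal form that
round-trips through a double, so write∘read is the identity on values,
geometry and nodata mask. Anisotropic (dx/dy) grids are rejected at read
time. Alignment offers nearest-neighbour (value of the source cell
containing the target cell center) and mean aggregation (average of
non-nodata source cells whose centers fall in the target cell); no
coordinate-system reprojection is attempted. Slope is the steepest of the
eight neighbour descents, 100·rise/run, with diagonal distance
cell_size·√2; pits and flats get 0.

## Production functions: discrete Bayesian networks

Networks are DAGs of discrete nodes with conditional probability tables
(last axis sums to 1 within 1e−9). Inference is exact variable
elimination; the test suite verifies it against full-joint enumeration on
hundreds of random ≤6-node networks. Training is additive (Dirichlet)
smoothing, entry = (count + α)/(parent count + α·k), default α = 1;
α = 0 gives maximum-likelihood frequencies, with unseen parent
configurations set uniform and logged. Structure learning is out of
scope: structures are user-supplied, and no accounting is attempted for
structural uncertainty.

Spatial application discretises continuous evidence rasters by per-node
strictly increasing bin edges (out-of-range values clamp to the edge
bins and are logged); nodata evidence is **marginalised, not imputed**,
so a cell with no evidence receives the target's prior marginal and a
correspondingly wider distribution — missing data shows up as higher
mapped uncertainty. Summaries are paired maps: expected midpoint with
coefficient of variation √var/|mean| for numeric nodes (0 for a
degenerate zero-mean cell; nodata when the mean is 0 with positive
variance), modal state with Shannon diversity −Σp ln p (natural log,
0·ln 0 := 0, ties to the lowest state index) for categorical ones. A
numeric node is by definition one with midpoints; nodes without
midpoints are categorical.

## Flow simulation

A flow problem is three aligned nonnegative rasters (source, sink, use),
benefit semantics, and a router. Simulation time is untimed: a single
sweep to quiescence, no time steps. The *possible* pass forces sinks to
zero; the *actual* pass runs them. Preventive benefits reuse the
provisioning mechanics with reversed interpretation (actual use = damage
received, blocked use = damage prevented); there is no separate code
path.

**Downslope (d8).** Each cell drains to its steepest strictly lower
8-neighbour (drop/distance; ties to the first direction clockwise from
East); pits, flats and nodata are terminal, and the graph is acyclic
because elevation strictly decreases along edges — descending elevation
order is therefore the topological processing order. Per cell, in order:
the sink absorbs min(throughflow, capacity); rival use withdraws
min(remainder, unmet demand) while non-rival use registers contact
without depletion; the remainder passes downstream. The sink-then-use
order within a cell is a declared convention (sinks interposed on the
path act before beneficiaries). Origin attribution is carried as a
sparse per-cell composition scaled proportionally at every absorption
and withdrawal. Carrier reaching a terminal is *exported*: accounted
neither delivered nor blocked, reported in the run log.

**Line of sight** (non-rival only). A use cell receives every source
within the distance limit whose center-to-center sight line clears the
terrain. The terrain profile is the piecewise-linear interpolation of
elevations where the ray crosses rows/columns of cell centers (each
crossing interpolated between the two adjacent centers); since the
profile is piecewise linear, checking the crossing vertices is exact.
Sinks act as ray-intercepting attenuators subtracting capacity from the
contribution with floor 0 — an additive convention, flagged for
revisiting, as a multiplicative transmissivity would also be defensible.
Contributions multiply by the use weight: delivered totals legitimately
exceed the in-situ supply when several users see one source.

**Access cost.** Users reach sources within a cost budget by 8-connected
least-cost distance (step = mean of endpoint costs, ×√2 on diagonals).
Rival allocation processes (user, source) claims in increasing cost
order, splitting exact cost ties over one source proportionally to unmet
demand; the withdrawal is grossed up by the remaining sink capacity on
the least-cost path so that delivery meets demand exactly, and path
sink capacities deplete in claim order. Non-rival users each receive
every reachable source in full, attenuated by path sinks without
depletion.

**Global mix.** A well-mixed pool Σsource − min(Σsource, Σsink) is
allocated to users proportionally to demand and capped by demand; flow
maps are the uniform pool density.

### Taxonomy identities and their edge cases

blocked_X = possible_X − actual_X and inaccessible source/use =
theoretical − possible (sink: theoretical − actual) hold exactly by
construction; rounding residues in (−1e−9, 0) are clipped. Three
structural edge cases are worth knowing:

* **blocked_source can be locally negative** under rival contention at a
  confluence: when a sink starves one branch, the proportional origin
  shares of a demand-limited withdrawal shift toward the other branch,
  whose delivered value then exceeds its possible-pass share. The signed
  values are kept (they are informative); the aggregate is verified
  nonnegative. Per-cell nonnegativity *is* guaranteed — and enforced —
  for the use, flow and sink maps of the supply-push routers.
* **Non-rival replication** can deliver more than the in-situ totals
  (one view, many users), so inaccessible source/use floor at zero — a
  no-op for rival problems, where possible ≤ theoretical is provable.
  Similarly, summed ray attenuation across non-rival paths is
  non-consumptive, so actual_sink records the capacity actually
  exercised, capped at the theoretical capacity.
* **Demand-driven withdrawal** (access routing) moves extra carrier to
  cover en-route absorption, so actual_flow can locally exceed
  possible_flow; blocked_flow floors at zero there (a no-op for the
  supply-push routers).

The conservation law actually guaranteed for rival downslope problems,
and asserted by the tests to 1e−6 relative, is
Σ theoretical_source = Σ actual_use + Σ actual_sink + exported.

Known simplifications: single-successor routing (no multi-direction
dispersion), no stream-network or infrastructure re-routing, no temporal
dynamics.

## Sustainability sweep

The simulation is re-run with demand scaled by each multiplier
(multiplier 1 inserted when absent); the supply ceiling is the largest
total delivered use observed, and the reported ratio is
100·ceiling/current-need rounded half away from zero to an integer
percent. A zero current need is an error, not an infinite ratio.

## Hybrid erosion

Annual soil loss is the factor product R·K·LS·C·P on cells with slope
≤ 20 % (strict comparison: the boundary cell is deterministic) and the
steep-slope network posterior above it. The fused result is a single
distribution layer over the network's erosion classes; gentle cells hold
a point mass whose per-cell midpoint is the exact deterministic value,
so the numeric summary reproduces the factor product with CV 0. Factor
derivation from primary data (rainfall→R, texture→K, DEM→LS) is out of
scope — factors are inputs. The shipped 4-node steep-slope network
(soil, precipitation, vegetation → erosion class, midpoints 5/50/200
t/ha/yr) is illustrative only and is expected to be replaced by a
locally trained model; it must not be read as any particular region's
calibrated model. Sediment concentration is delivered mass over
delivered water volume; regional contrasts are plain concentration
ratios.

## Monte-Carlo uncertainty

Cells are sampled independently — no spatial copula; spatially
correlated input uncertainty is a known limitation, so mapped CVs
understate the variance of regional aggregates when true errors are
correlated. One master seed drives everything; per-draw generators come
from `SeedSequence(seed).spawn`, making runs platform-reproducible
(integer-state sampling only). Running means and variances use Welford
accumulation; an optional wall-clock budget aborts cleanly with the
partial result flagged invalid. Closed-form (variance-propagation)
results are provided only for the global-mix router in its linear regime
(total sink below total source, demand caps slack), where delivered use
is linear in the independent cell draws; a warning is raised when the
regime fails at the mean. Everywhere else Monte Carlo is authoritative.

## Model assembly

Ontology reasoning is replaced by ordered specificity tag paths; the
six ranking criteria are each normalised to [0, 100] with declared
conventions: matched tag-path depth fraction (semantic specificity),
context-extent coverage fraction (scale), ctx-to-candidate cell-size
ratio capped at 1 (detail), same/different source ontology → 100/50
(semantic distance), period-coverage or overlap fraction (currency), and
the user rank, defaulting to 50 when unset. Weights are configuration,
uniform 1/6 by default, normalised to sum 1. Ranking ties break by finer
resolution then lexicographic id, so assembly is auditable and
replayable; re-resolving from the same registry and context reproduces
the identical provenance. Context predicates (`var op number`) guard
candidates on scalar or raster context variables; raster guards
partition the grid, so one concept may resolve to several candidates
over disjoint segments — this is exactly how the gentle/steep erosion
pair assembles. Scenario overrides are appended with maximal priority,
leaving the baseline registry untouched; everything that requires the
overridden concept re-resolves to the scenario candidate.

## Scenario reports

Comparison tables report the percent change of each output-map **total**
(not the cellwise mean — so the figures are not invariant to changes in
the nodata footprint), rounded half away from zero to one decimal,
locale-independently; zero-baseline rows print as "n/a", never infinity.

## Synthetic landscapes

The generator exists so that every capability is testable with no
external data. Terrain is seeded white noise smoothed by iterated 3×3
averaging (chosen over spectral synthesis for platform-stable
determinism), rescaled to an exact relief standard deviation, plus an
eastward tilt that guarantees the flow graph an outlet; land cover grows
from seeded patches (expected patch size in cells is the control); the
source/sink/use surfaces take per-class intensities, so their totals
have closed forms used in assertions. Defaults — 24×24 cells of 30 m,
50 m relief, four cover classes, source-heavy uplands and
use-heavy lowlands — sketch a Landsat-scale hilly watershed. What
passing tests on these fixtures show is the correctness of the
machinery: routing, accounting identities, inference, recovery and
calibration. What they do not show is realism of any real region's
statistics — real evidence layers are correlated, anisotropic and
scale-dependent in ways the generator deliberately does not emulate.

## Problem sizes in the default suite

Oracle-equivalence checks run on 200 random 5×5 flow problems, 200
random ≤6-node networks and 50 random 8×8 terrains; identity and
conservation checks on 5×5 problems and 12×12 landscapes; parameter
recovery on 10⁴ sampled cases; Monte-Carlo calibration on a 1×3 strip at
2 000 draws. These sizes were chosen because every property being tested
is scale-free — the oracles are exact at any size, and small grids let
the whole suite run in seconds while exercising every code path.
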