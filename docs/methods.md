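# Methods

## Scope and structure

The package separates three layers that can be exercised independently:

1. **Demand cascade** (`sites`, `sampling`, `demand`) — archaeological
   inputs to annual material, labour and land requirements. Runs without
   any landscape; `montecarlo.demand_ensemble` propagates all priors at
   ~10⁴ draws per second-scale runtimes.
2. **Supply** (`landscape`, `transport`) — the age-structured raster
   woodland and the transport-cost orderings that decide felling order.
3. **Coupling** (`engine`, `montecarlo`) — the annual loop, the stopping
   rules, ensembles and summaries.

`synthetic` generates complete test scenarios so that every stage is
exercisable without any external download.

## Sampling model

All interval-bounded parameters follow the principle of insufficient
reason: a normal centred on the interval midpoint with a standard deviation
of one sixth of the interval length, truncated to the interval by
rejection. Rejection (rather than clipping or inverse-CDF truncation)
keeps the distribution shape inside the bounds and mirrors the redraw rule
used for the dating windows; with ±3σ spanning the interval the acceptance
rate is ≈99.7 %, so the cost is negligible.

Furnace inefficiency is right-skewed: a lognormal whose underlying
parameters are moment-matched to the stated arithmetic mean 5.25 and s.d.
1.75 kg/kg, truncated to [2.0, 8.5]. Moment matching is one of two
defensible parameterisations (the other being a normal on the log of the
bounds); the choice shifts the median from ≈4.9 to ≈4.1 kg/kg and is the
single most influential convention in the whole model. It is isolated in
`draw_furnace_inefficiency` should users want the alternative.

Kiln technology: `kiln_mode` draws a pit or earth-mound kiln per run
(`mixed`, p(mound)=0.5 by default) or pins the type. The two types differ
roughly twofold in wood per unit charcoal, so this switch dominates total
wood demand after furnace inefficiency. The analysis scripts and the
acceptance computations use the `mound` preset, which reproduces the
effective technology of the published headline configuration.

Rounding of sampled years: nearest integer, ties away from zero. Years are
signed integers (−300 = 300 BCE) on a continuous axis; no year-zero
correction is applied.

## Dating windows

Multi-find sites: the outer window is the envelope of the find intervals,
the certain interval the smallest interval meeting every find. For
overlapping finds this can be empty (max aᵢ < min bᵢ); the window is
repaired by collapsing the certain interval to its midpoint with a warning,
which keeps windows valid without inventing precision. Single-find sites
use the central half of the find's interval as the certain interval.

## Labour and land

The cascade sizes each occupational group from one year's flows with the
per-capita annual productivities, rounds each group up to whole people,
then applies +30 % supervision on the human core subtotal and +30 % service
on core + supervision (service supplies everyone, including supervisors; an
additive variant is a config flag). Charcoal-burner batches are measured in
tonnes of wood charged (3.5 t/batch for pit kilns at 12.5 person-days,
45 t/batch for mounds at 25 person-days), converted to capita at 250
working days per year (config key). Transport animals are not people: they
are excluded from the human total but drive driver counts (1 per 5
animals) and pasture area (0.8–1.1 ha per animal, drawn per run). Miners
are sized from the full regional ore extraction (0.97–3.67 Mt over the
mining chronology, by default a plateau-trapezoid intensity profile peaking
in the intensive phase) but excluded from the headline workforce total;
their households still burden the island's endosomatic demand by default
(`include_mining_endosomatic`). Household fuel is charcoal and is by
default produced at the run's kiln productivity; a raw-wood variant is a
flag.

The engine-free peak-workforce statistic converts wood demand to felled
area with the mature (42-yr) macchia stock per hectare, matching a
simulation that starts from undisturbed woodland; fellers are <1 % of the
total, so this convention is immaterial to the headline number.

## Growth and supply

Standing volume per vegetation class is logistic,
V(a) = C·(σ(k(a−a₀)) − σ(−k·a₀)), with V(0)=0. Two constraints anchor it —
V(10)/10 equals the class's 10-yr mean annual increment, and V(42) reaches
99 % of the asymptote — and the inflection age a₀ = 21 yr (mid-span of the
42-yr maturity horizon) fixes the remaining degree of freedom; k then has
the closed form σ(21k) = 1/1.01, solved numerically for generality. The
resulting mature stocks (oak ≈300, macchia ≈490, chestnut ≈780 m³/ha) are
upper-end figures for these formations; they matter only for the spatial
stages, and lowering them uniformly raises shortage likelihoods.

Harvest zeroes a cell's age; regrowth adds one year per year, capped at 42.
Browse-flagged cells are zeroed on first assignment and then accumulate
age at the reduced rate (1 − browse reduction) via a fractional-age
accumulator; both mechanisms are separately switchable for sensitivity
runs. Grassland in the vegetation source is treated as macchia at
initialisation.

Non-wood land (farmland, pasture) converts cells in a fixed priority order:
open (unwooded) land first, then by gentler slope, then by proximity to the
nearest site — farmers take the plains before clearing forest, and workers
live near their worksites. Assignments are redone from the same order each
year, so a shrinking requirement releases the most expensive cells first.
Unmet land requirements contribute to the shortage signal.

## Transport and felling order

Felling preference is transport cost over the straight segment from site to
cell: Euclidean distance and the mean slope raster value sampled at 33
points along the segment (a documented fidelity limit — no least-cost
routing). Walking speed is Tobler's hiking function; the metabolic rate is
the Pandolf equation with the Santee downhill correction, floored at the
standing term. The load-carriage constants (70 kg body, 20 kg load,
terrain factor 1.2) only scale the cost, and the *ranking* — the only thing
the engine consumes — is insensitive to them at fixed slope–distance
trade-off; travel time is an alternative ranking key. Ties break by
distance, then row-major cell index, so orderings are deterministic and
seed-free.

## Engine

Years run from the earliest sampled site start to the latest end. Within a
year, sites act in ascending id order (an optional seeded shuffle
quantifies order sensitivity); each walks its cost ordering over cells
older than the rotation period, felling until its requirement — furnace
wood plus its slag-proportional share of household wood — is met, taking
the final cell whole. Shortage is flagged the first year a requirement
stays unmet although no eligible cell remains anywhere, and the run stops
(complete deforestation). Endosomatic land is allocated after felling;
regrowth closes the year. With identical draw and inputs the records are
bit-identical across repeats.

## Ensembles and summaries

Likelihood is the raw fraction of runs with a shortage (a Wilson 95 %
interval is reported alongside), mapped to the calibrated verbal scale
(virtually certain >99 %, … , unlikely <33 %, …, exceptionally unlikely
<1 %; the most specific band wins). Scalars are summarised as median ±
unscaled median absolute deviation; interval statements use central 67 %
and 95 % quantiles. Timing statistics of an annual series pad it with one
implicit zero on each side (so onset and shutdown count as changes), take
the argmax and the extreme first differences, and resolve ties to the
earliest year (flagged). Exo and full-metabolism ensembles at the same
seed share their parameter draws run for run (common random numbers), which
makes the likelihood ordering a per-run superset property rather than a
statistical one.

The published felling-timing quantities are properties of the simulated
felled-*area* series, not of the demand series: demand is piecewise
constant with a long near-plateau whose argmax sits right after the
strongest increase, whereas felled area keeps creeping upward through the
plateau as mature stands exhaust and harvesting shifts to younger, lighter
stands — so the area maximum lands a few years before the decline. The
acceptance computations therefore take the timing targets from the
engine's area series; the demand-series timing is computed and tested too
(its strongest-increase and strongest-decrease years coincide with the
published ones).

## Synthetic data

`make_island` builds spatially coherent landmass, elevation/slope and
vegetation patches from smoothed Gaussian noise with a radial taper
(guaranteed coastline), reproducible from the seed. `place_sites` spreads
sites around the shoreline by angle and either carries the packaged
29-site catalogue verbatim (`elba_like` preset: ~224 km² of land at the
chosen working resolution, macchia-dominant mix 55/25/8 %, twelve angular
regions) or generates dating finds along a production arc — few small
early sites, many larger intensive-phase ones. `stock_to_demand_ratio`
rescales slag bounds so initial dry stock over expected mid-parameter wood
demand hits a target; the `abundant` (ratio 10) and `scarce` (ratio 0.1)
presets bracket the shortage regimes for calibration tests.

What the generator does *not* emulate: the real island's coastline and
relief, the true spatial covariance of vegetation with topography and
exposition, the actual placement of sites relative to the wood-rich
interior, and any mainland exchange. Passing tests on synthetic islands
therefore validate the machinery and its qualitative behaviour (likelihood
ordering, calibration regimes, timing structure), not the real-map
likelihood values, which require the original vegetation raster.

## Problem sizes

The analysis scripts and tests run at desk scale by choice: engine-free
propagation at 10⁴ draws; spatial ensembles of 60–300 runs on the
Elba-scale island at 250 m working resolution (the resolution is a
parameter; finer grids change cell granularity, not totals, since slag
masses are area-independent). The original study's scale — ~11.5 k runs at
10 m — is a documented large preset, not the default.

## Known limitations

* No species selection, soil degradation, erosion feedback, climate-driven
  growth change, or seasonality (annual resolution).
* Workforce absolute scale depends on furnace-crew conventions that are
  only partially documented in the public record; the occupational *shares*
  are robust, the absolute peak total carries a factor-scale uncertainty
  (see the worked numbers in the README).
* Straight-segment cost surfaces, not least-cost paths; sea transport
  enters only as labour counts.
* Monophasic site activity and time-constant technology per run.
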