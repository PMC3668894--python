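# Methods

## Model

The simulation is a discrete-time (daily) agent-based model of school
commute mode choice on a stylised city. Space is a square grid of roads
discretised into cells; households, schools and walking routes all live on
road cells. One child per household chooses between walking and being
driven each morning. The choice couples a *threshold* rule on perceived
traffic safety with a *compensatory* rule on attitude and distance:

* walk only if the route's mean cell safety strictly exceeds the
  household's fixed concern threshold `C_t ~ U(0,1)`;
* and only if attitude plus distance-decay propensity strictly exceed one,
  `A_w + exp(-beta * d) > 1`, so a long commute can be offset by a strong
  attitude and vice versa.

Per-cell safety follows a safety-in-numbers law, `S = 1 - W**-0.6`
(clamped to [0, 1]): `W**-0.6` is an empirical estimate of the
per-pedestrian probability of being struck by a car when `W` pedestrians
are about, so safety rises with pedestrian volume with diminishing
returns. `W` on a cell is yesterday's count of walking children whose
routes traverse the cell, plus a constant background volume. Attitudes are
rescaled daily by the school-level social-norm ratio
`(0.9 + 0.1*Nw'/N) / (0.9 + 0.1*Nw/N)` and clamped to [0, 1]; a school
where walking increased yesterday nudges every enrolled child's attitude
upward by at most ~11%.

Assumptions worth keeping in mind: concerns are fixed for ever; routes and
school assignments are fixed at initialisation; only walking children and
the uniform background affect safety (driving parents do not degrade it);
walking and driving are the only modes; every household has exactly one
child.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `city_size_m` | 8000 | m | city edge length |
| `n_roads_per_axis` | 41 | — | grid roads per direction (41 × 41) |
| `segments_per_road` / `cells_per_segment` | 40 / 10 | — | a segment is 200 m = 10 cells of 20 m |
| `n_schools` / `n_households` | 4 / 3000 | — | enrolment and density of the baseline city |
| `beta` | 1.6 | per mile | distance decay of walking propensity |
| `background_walkers_per_cell` | 1.5 | walkers/cell/day | ambient pedestrian volume |
| `max_days` | 100 | days | convergence guard |

`beta` and the background density are the two calibrated quantities: the
`calibration` module grid-searches them jointly (seeded, exhaustive,
unweighted sum of squared per-band differences) against the built-in NHTS
2009 walk-share-by-distance table. The middle-school column is the default
reference since the simulated schools are middle schools. With the default
grids the search lands on (1.6, 1.5), and a self-recovery property (target
generated by the model itself at a grid point, same replicate seeds) is
exact because the objective is identically zero at the truth.

The initial safety everywhere is `1 - 1.5**-0.6 ≈ 0.216`, so on day 1
roughly a fifth of households clear the safety condition; the feedbacks
then roughly triple the walking share before settling.

## Geometry and routing choices

* Roads sit on segment boundaries, so `n_roads_per_axis` must equal
  `segments_per_road + 1`; intersections are single shared cells. The
  default grid has 2·41·401 − 41² = 31 201 road cells.
* Households and schools occupy distinct road cells, sampled without
  replacement (occupancy is exclusive; nothing in the model needs two
  agents on one cell).
* Routes are canonical shortest paths: along the origin's road first, then
  the cross road, with fixed fallbacks for mid-segment endpoint pairs that
  need a detour through a cross-road (the only case where network distance
  exceeds Manhattan distance; it cannot occur when a school sits on an
  intersection, as all evenly-placed schools do). A deterministic canonical
  route keeps runs bit-reproducible. We also implemented randomised
  monotone staircase routes (one seeded draw per child) to test whether
  concentrating walkers on L-paths distorts the feedback; steady-state
  walking shifted by under 0.15 percentage points over 20 replicates, so
  the simpler canonical path is kept.
* The distance used in the decay rule and the reporting bands is network
  distance in miles (1 mile = 1609.34 m), the same metric the route-safety
  average is taken over. Bands are half-open `[lo, hi)`.
* Zone partitions for school placement: 2 → 2 × 1, 4 → 2 × 2, 6 → 2 × 3,
  8 → 3 × 3 with the centre zone left without a school. Cells exactly on a
  zone boundary belong to the lower-indexed zone; zone-centre schools snap
  to the nearest road cell (Euclidean, ties to the lexicographically
  smallest coordinate). Nearest-school ties go to the lowest school id,
  which makes the evenly-placed nearest-school and own-zone catchments
  coincide exactly.

## Scheduling and numerical choices

* Day `t` decisions use safety computed from day `t−1` walker counts
  (day 1 uses background only), breaking the simultaneity between the
  decision rule and the safety law. Walker tallies `N_w`/`N_w'` start at
  zero, so the first social-norm update divides by the bare 0.9 base.
* Each walking child adds exactly 1 to every cell of their route per day
  (the one-way trip; the calibrated background absorbs the overall scale).
  Counts are real-valued since the background is 1.5.
* Attitudes are clamped to [0, 1]; the norm ratio can otherwise push them
  above 1. Safety is clamped after adding the intervention boost.
* Convergence: stop on the first day that completes three equal
  consecutive daily walker counts ("constant for two consecutive days");
  a 100-day guard flags (but does not raise on) non-convergence. Baseline
  runs converge in 6–10 days; period-2 oscillations have not been observed
  but would hit the guard rather than loop forever.
* Intervention boosts use Euclidean discs around schools (the 0.5 / 0.71 /
  1.0-mile radii double/quadruple the disc area, which is what the
  `a · (0.5/r)²` intensity scaling holds constant); overlapping discs take
  the maximum boost, not the sum, to keep increments within [0, 1].
* Scenario and intervention contrasts reuse the same replicate seeds
  (`base_seed + i`) across arms, so differences are policy-driven.

## What the generator does and does not emulate

The synthetic city reproduces the *structural* conditions of the study
design: uniform household scatter, grid connectivity, catchment geometry
and survey-calibrated behavioural parameters. It does not emulate real
cities: no heterogeneous densities or land use, no non-grid topology, no
household heterogeneity beyond the two uniform draws, no bicycling, school
buses, sibling effects, weather or crime. Passing tests therefore show the
mechanics and feedbacks are implemented correctly and reproduce the model's
known behaviour under its own idealised conditions — not that the
quantitative levels transfer to any real city.

## Problem sizes

Experiments default to 20 replicates of the full 3000-household city
(~0.1 s per replicate after the ~0.2 s city build). The test suite uses the
full scale for the reproduction checks (scenario suite, 16-cell density
grid, nine intervention strategies) and small cities (3–600 households) for
unit, property and oracle-equivalence tests; calibration self-recovery runs
a 3 × 3 grid at 2 replicates on a 600-household city, which is sufficient
because the self-recovery objective is exactly zero at the generating
point regardless of scale.

## Known limitations

* Unstated implementation details of the behavioural scheduling (exact
  trip counting entering the safety law, update ordering) leave a small
  systematic latitude in steady-state levels — a uniform shift of roughly
  one percentage point across scenarios in our measurements — while
  orderings, distance distributions and band profiles are insensitive to
  them. Contrasts between scenarios are the robust output; absolute levels
  inherit this latitude.
* The canonical route concentrates each child's contribution on one
  shortest path; cell-level walker counts (not reported) are therefore
  more peaked than under route mixing, though aggregate outcomes are not
  measurably affected (see above).
* Safety responds to walkers only; the possibly detrimental traffic effect
  of driving parents is outside the model.
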