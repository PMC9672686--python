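# Methods

## The heat-stress budget model

The model treats pedestrian heat strain as a dose that accumulates
linearly in time at a rate set by the heat-stress level of the current
street segment. UTCI (an equivalent temperature summarising air
temperature, humidity, wind and radiation) is banded into levels 0–4 at
breakpoints 26, 32, 38 and 46 °C — no / moderate / strong / very strong /
extreme heat stress. Walking a segment of level `L` for `t` minutes adds
`L·t` stress-minutes to the cumulative dose `S_t`; the remaining tolerant
heat discomfort is `R_t = H − S_t` for a budget `H`. The model's
assumptions, made explicit:

- **Linearity and additivity.** Dose rate depends only on the current
  level, not on history; levels act as integer multipliers of time.
- **Worst-case segment exposure.** A segment whose UTCI varies along its
  length is scored at its maximum UTCI. Streets with genuinely mixed
  conditions should be split into separate features, which is how the
  bundled example route is built (sections a–h).
- **Conservative boundaries.** A UTCI exactly on a breakpoint takes the
  higher level, and durations round *up*, so the model never understates
  the dose.
- **No cold side.** All UTCI at or below 26 °C is level 0 and
  contributes nothing; cold discomfort is out of scope.
- **No recovery by default.** Time at level 0 neither adds nor removes
  stress. A `recovery_rate` (stress-minutes recovered per level-0
  minute, floored so `S_t ≥ 0`) exists as an explicit extension for
  users who want an alleviation phase; the applied model keeps it at 0
  because no empirical alleviation rate is available.

Past exhaustion (`R_t ≤ 0`) the trajectory keeps accruing negative `R_t`
and flags the first exhausted segment rather than truncating — downstream
consumers decide what "people must stop and rest" means for them.

### Parameters

| parameter | unit | default | why |
|---|---|---|---|
| breakpoints | °C | 26, 32, 38, 46 | standard UTCI heat bands |
| `H` | stress-min | 60 | survey calibration at level 4 (see below), upper end of [52, 60] |
| `walking_speed` | m/s | 1.0 | typical adult walking pace used in FMC accessibility work |
| `time_quantum` | min | 0.1 | resolution of the published duration tables; ceil rounding |
| `recovery_rate` | stress-min/min | 0 | alleviation unquantified |
| `budget_m` | m | 900 | 15 min × 1 m/s |
| `R_t` bins | stress-min | 45/30/15 | display and siting bands 45–60, 30–45, 15–30, 0–15, exhausted |

The duration rule is pinned by the published worked example: 44.8 m at
1 m/s is booked as 0.8 min, which only round-up reproduces (plain
rounding gives 0.7). `S_t`/`R_t` are kept in stress-minutes (level ×
minutes), not minutes; the two coincide only at level 1.

## Route search

Routes are simple paths on an undirected street graph with positive edge
lengths; each edge's stress cost is `level × quantised duration`. The
best route maximises terminal `R_t`, i.e. minimises path stress, subject
to total length ≤ budget, with ties broken by shorter distance and then
lexicographic node order for determinism.

Correctness argument: removing a cycle from any walk strictly reduces
distance and never increases stress, so the optimum over walks equals
the optimum over simple paths, and Pareto label-setting over
(stress, distance) states with dominance pruning is exact. The
walkability map asks a subtler question — for each edge, the best
terminal `R_t` over routes that *end by traversing that edge* — so its
labels also carry visited sets and a label is pruned only by a dominating
label whose visited set is a subset (any extension of the pruned label is
then available to the dominator at no extra cost). The optional
`statistic="min"` (worst route over an edge) cannot use dominance pruning
at all and enumerates budget-bounded simple paths exhaustively; it is
exponential in the worst case and intended for small graphs. Both
searches are validated against an independent depth-first enumeration
oracle in the tests.

Edges the budget cannot reach are flagged unreachable rather than scored.
When several neighbourhoods' maps are aggregated, the district score of
an edge is the population-weighted convex combination of the `R_t` values
of the neighbourhoods that reach it, with weights renormalised over that
subset. Treating unreachable origins as `R_t = 0` instead is offered
behind a flag; renormalisation is the default because an entrance that
cannot reach a street within 15 minutes says nothing about how stressful
that street is. Only population ratios enter the weights, so populations
may be supplied in persons or thousands.

## Survey calibration of H

The calibration protocol walks respondents for 15 minutes at each
constant stress level, recording an ordinal discomfort rating
(1 slightly … 4 extremely uncomfortable) every minute. The per-minute
panel aggregate is the **upper median** (ties resolve to the worse
category) — a deliberate design choice: the group-level bands such
surveys report do not state their aggregation rule, and the median is
the standard robust summary for ordinal data; resolving ties upward
matches the model's conservative bias. Category onsets are the first
minute whose aggregate reaches the category; they are nondecreasing in
the category by construction.

`H` follows from the extreme-stress condition: if extreme discomfort
sets in at minute `m` of the 15-minute protocol at level 4, the
tolerable dose lies in `4 × [m, 15]` stress-minutes. With the default
generator onsets (extreme at minute 13) this is [52, 60]. The reported
value is a policy choice — `upper` (aspirational, default), `midpoint`
or `lower`. Note the distinction between the *pre-extreme tolerated
duration* (`m − 1` minutes) and the *calibration band* (`[m, 15]`): the
band, not the pre-onset duration, is what the dose arithmetic uses.

Internal consistency of each level's 15-minute item series is summarised
by Cronbach's α, `α = k/(k−1) · (1 − Σ var(item) / var(total))` with
sample variances. α is undefined (reported as NaN per level) when the
total score has zero variance, e.g. a noiseless panel.

## Synthetic data: what it emulates and what it does not

The UTCI field generator reproduces the *statistical* signature of a
late-afternoon summer UTCI map of a dense subtropical district — values
mostly in the strong/very-strong bands (clipped to 28–44 °C), smooth
spatial correlation (Gaussian-filtered noise with a correlation-length
parameter; a formal variogram model would be overkill for fixtures),
a cooler riverside strip (−3 °C), scattered tree-shade blobs (−2.5 °C,
top-quintile threshold of a second smoothed field) and periodic
east–west canyon rows (+3 °C). The masks are mutually disjoint so the
additive effects are identifiable. It is **not** a physical model: no
radiation geometry, no diurnal cycle, no wind. Passing tests therefore
show that the pipeline arithmetic is correct on fields with realistic
range and spatial structure, not that any particular city's UTCI map is
reproduced.

The survey generator emits each respondent's true category (a step
function of the per-level onset minutes; defaults: level 1 never leaves
"slightly", level 2 onset 9, level 3 onsets 6/12, level 4 onsets 5/8/13)
flipped one ordinal step up or down with probability `noise_prob`
(default 0.1, clamped to 1–4), for 128 respondents. Respondents are
exchangeable — there is no between-respondent heterogeneity — so the
generator supports onset-recovery tests but deliberately does not
reproduce the high between-respondent reliability (α ≈ 0.93) that real
panels show; α's behaviour is instead verified against closed forms and
a null simulation. All generators are pure functions of (spec, seed).

Network generators build grid (rows × cols blocks, so
(rows+1)(cols+1) intersections; rows=0 degenerates to a chain), chain
and radial layouts in planar metre coordinates. Geographic CRS support
is intentionally absent: study areas of interest are ~1 km across.

## Numerical choices

- Durations quantised by `round(k)` when within 1e-9 of an integer
  multiple of the quantum (guards against float dust such as
  12 m → 0.2 min), else `ceil`.
- Stress sums and `R_t` traces rounded to 9 decimals at each step; all
  budget and dominance comparisons use a 1e-9 slack.
- `R_t` bins and siting classes are half-open with the boundary going
  up (45.0 → the 45–60 bin), mirroring the breakpoint convention.
- GeoJSON endpoint snapping merges nodes within 0.5 m by default;
  explicit `from_node`/`to_node` properties bypass snapping.

## Problem sizes

The test suite and reproduction script run the worked example (7
segments), route-search fuzzing on 200 random graphs of up to 10 nodes
against exhaustive enumeration, walkability-map fuzzing on 40 graphs of
up to 7 nodes for both statistics, survey-recovery simulation over 100
seeds × 128 respondents, and an end-to-end 10×10-block pipeline run —
sizes at which the exhaustive oracles are exact and the whole suite
completes in seconds on one core.

## Known limitations

- `H` is a single scalar; tolerance differences across demographic
  groups (children, older adults, pregnant women) are not modelled.
- Edge UTCI is static during a traversal; no time-of-day variation.
- Stress levels are integers; sub-band variation within a UTCI band is
  invisible to the dose.
- The walkability map's `min` statistic is exponential-time.
- Computing UTCI itself from meteorology is out of scope; the package
  consumes UTCI values produced elsewhere.
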