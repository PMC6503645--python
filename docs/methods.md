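# Methods

## Model and assumptions

The analysis operates on two-dimensional stroke-care geographies in
which the coordinate unit is driving time (minutes). This is equivalent
to assuming one transport mode and homogeneous traffic/weather/road
quality across the incident region, so that travel time is proportional
to distance; with that assumption, travel time between any two points is
the Euclidean distance between their coordinates. All PSCs are assumed
comparable in door-to-needle and door-in-door-out (DIDO) performance —
heterogeneous per-center treatment metrics are explicitly out of scope.

Random geographies: a "homogeneous spatial Poisson point process in the
disc" with fixed center counts is, conditionally on the counts, an
i.i.d. uniform sample on the disc. We therefore draw each center as
(R·√U·cos Θ, R·√U·sin Θ) with U ~ U(0,1), Θ ~ U(0, 2π). CSC and PSC
positions are drawn from the same law, independently — no
inhibition/attraction between centers is modeled. Disc radii of 30 and
120 min represent dense (urban-like) and sparse (rural-like) center
densities; any positive radius is accepted.

## Admissible destinations

For a scene `s` with nearest-CSC time `d_CSC`, a PSC `j` with scene time
`d_j` and best transfer time `t_j` (the minimum over CSCs of the PSC→CSC
driving time) is **admissible** iff

1. `d_j < d_CSC` (otherwise direct CSC transport dominates the PSC on
   both the thrombolysis and the thrombectomy axis), and
2. no PSC `l` with `d_l < d_j` has `d_l + t_l ≤ d_j + t_j` (a strictly
   scene-closer PSC reaching a CSC at least as fast leaves the farther
   PSC without any strict benefit).

The admissible set is the strict Pareto staircase of (scene time, via
time): sorted by scene time the via times strictly decrease. The
formal definitions behind the original sub-region construction were
published only in supplementary material that is not reproduced here;
the rules above are reconstructed operationally from the main text and
validated against an independent O(n²) all-pairs dominance filter in the
test suite. Tie handling (measure-zero events under the continuous
sampling model) is by strict dominance: an equal-via farther PSC is not
admissible, and a location equidistant between a CSC and a PSC counts as
unconditional CSC catchment. Comparisons use exact floating-point
arithmetic with no epsilon, since travel times are smooth functions of
position and exact ties do not occur in simulation.

Locations are labelled by option count (1 + number of admissible PSCs):
`UNCONDITIONAL_CSC` (1), `SIMPLE_TRIAGE` (2), `HIGHER_ORDER` (≥ 3).
The triage region is everything except the unconditional catchment,
equivalently all points whose nearest center is a PSC.

## Benefit/harm ratios

Both ratios are evaluated per *additionally considered* PSC — each
admissible PSC beyond the nearest one; the nearest PSC is the
drip-and-ship default, not an "additional" option, and carries no
ratio. With nearest-PSC times `(d_1, t_1)` and option times `(d_2, t_2)`:

* `BHR_PSC = [(d_1 + t_1) − (d_2 + t_2)] / (d_2 − d_1)` — thrombectomy
  minutes gained per thrombolysis minute lost vs the nearest PSC. DIDO
  cancels because it is identical at both PSCs.
* `BHR_CSC = (d_CSC − d_2) / [(d_2 + DIDO + t_2) − d_CSC]` —
  thrombolysis minutes gained per thrombectomy minute lost vs direct
  CSC transport. DIDO enters only here.

Per point, the maxima over the additionally considered options summarize
the location ("the best available trade"), tracked separately for the
two ratio types since they answer different clinical questions (and are
mapped as two separate spatial fields).

When the BHR_CSC denominator is ≤ 0 the via-PSC route reaches the CSC no
later than direct transport, the harm axis vanishes, and no finite ratio
exists. Such options return a `DOMINATES` sentinel; points carrying at
least one such option are flagged, excluded from the BHR_CSC spatial
median (an infinite ratio would corrupt it), and reported separately as
`dominates_fraction`. Whether the original analysis included such points
in its medians is unstated; this exclusion is our convention and is only
consequential for large regions (it requires `d_CSC > via + DIDO`, which
is impossible at radius 30 with DIDO 60 since `d_CSC ≤ 60` there).

## Rasterization and statistics

Each environment is evaluated on a square lattice of pitch `step`
clipped to the incident region (node kept iff inside or on the
boundary). The default pitch is R/100 — at that resolution the lattice
area matches the disc area to within ~1% and halving the step moves the
reported fractions by well under one percentage point (both properties
are asserted in the tests). Area fractions are lattice point-count
fractions with no cell-boundary weighting; spatial medians and IQRs of
the per-point BHR maxima are taken over higher-order points, with
linear-interpolation quantiles (`numpy.percentile` default).

The replicated study draws 50 environments per (CSC, PSC) combination —
CSC 1–4 × PSC 2–10 gives 36 combinations — and aggregates
across-replicate medians and IQRs of each per-environment statistic.
Replicate `r` of combination `(c, p)` uses an independent RNG stream
keyed by `(master seed, c, p, r)` (numpy `SeedSequence` spawn keys), so
any single replicate is reproducible in isolation. Environments with no
higher-order points yield absent (NaN) BHR statistics and are omitted
from BHR aggregation, never counted as zero. Pooled "across all
scenarios" BHR statistics pool the per-environment spatial medians over
all combinations with equal weight per environment; the original
pooling weight is unstated, and for the pooled radius-30/120 split the
scale-free BHR_PSC is unaffected while BHR_CSC is reported per radius.

Scale behaviour, verified by property tests: multiplying all coordinates
(and the radius and step) by λ > 0 leaves labels, area fractions and all
BHR_PSC statistics unchanged; BHR_CSC statistics change unless DIDO is
scaled along, and BHR_CSC is strictly decreasing in DIDO. DIDO
sensitivity uses the set {30, 60, 90} min around the 60-min base case.

## Clinical cutoff

A patient with LVO probability `p` is expected to benefit from an
admissible non-nearest PSC when `BHR_PSC > (1 − p)/p × E_lysis/E_MT`,
strict inequality (no benefit at equality). The default per-minute
outcome effects — 1.8 (thrombolysis) and 4.2 (thrombectomy)
disability-adjusted life-days per minute of faster treatment — follow
the published estimates of Meretoja and colleagues; both are
configurable, and the cutoff depends on them only through their ratio.
The rule presupposes that the patient is not being triaged directly to
the nearest CSC anyway.

## Loaded geographies (realworld mode)

User geographies are CSVs of centers (`id,level,lat,lon`, or
`id,level,x,y` for planar data). Travel times come from a
constant-speed haversine model (default 60 km/h with road factor 1.3,
i.e. road length ≈ 1.3 × great-circle distance) or from a precomputed
center-to-center travel-time matrix; with a matrix, transfer legs use
the stored entries while scene legs (raster points are not matrix
entries) use the geometric model. The incident region is the centers'
bounding box plus a 10% margin, rasterized in coordinate units
(degrees); at city/state scale the latitude/longitude anisotropy mildly
distorts areas, which is acceptable for the qualitative maps this mode
produces. Live routing-API travel times are out of scope.

## Synthetic data vs reality

The generator reproduces the *abstract* study conditions: uniform center
placement, travel time = Euclidean distance, identical PSC performance,
homogeneous conditions in the region. Real stroke systems violate all
four (clustered hospitals, road networks, asymmetric and
traffic-dependent times, heterogeneous DIDO), so passing tests show the
decision geometry and its statistics are computed correctly under the
stated model — not that a specific real region has, say, a 52%
higher-order area. The realworld mode exists to re-run the same
machinery on actual center tables with better travel-time inputs.

## Problem sizes and numerical choices

Replicated-study computations in the tests and the reproduction script
use 50 replicates at lattice pitch R/100 (~31,400 points per
environment, ~1,800 environments for the full grid), evaluated with a
vectorized kernel (~50 ms per environment); the full study completes in
well under a minute. Degenerate inputs are rejected with validation
errors (non-positive radius/step/DIDO/speed, missing CSC, duplicate
ids); an all-CSC environment is valid and yields a triage fraction of 0
with absent BHR statistics.

## Known limitations

* Euclidean/haversine travel times ignore road networks and congestion.
* Identical DIDO and door-to-needle times across PSCs.
* Area statistics are lattice approximations, not exact polygon areas.
* No patient-level outcome modelling beyond the linear per-minute
  effects in the cutoff; no modelling of patient-volume shifts between
  centers.
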