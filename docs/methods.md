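# Methods

## Model and procedure

The package treats a stream of dated, geolocated events as realizations of
a spatiotemporal process whose causal structure is visible only at an
appropriate resolution. The analysis fixes a scale pair — temporal bin
width *a* in days and typical Voronoi cell radius *b* in km — and proceeds
in stages. All stages are deterministic given a master seed.

**Discretization.** The region (a lon/lat polygon on the WGS84-radius
sphere) is partitioned into pseudorandom Voronoi cells: centers drawn
uniformly (by spherical area) inside the region, relaxed by two
Monte-Carlo Lloyd iterations, with cells defined by great-circle
nearest-center assignment. Irregular cells avoid the directional artifacts
a regular lattice would imprint on neighbor statistics; the ensemble over
center draws later supplies the uncertainty measure. The number of centers
is `area / (1.47 b²)`, which makes the mean nearest-neighbor center
spacing equal *b*; the constant was calibrated once by simulation (pure
Poisson centers give spacing `0.5·sqrt(area/n)`; two Lloyd iterations
regularize it to `~0.82·sqrt(area/n)`) and is fixed in the source.
Adjacency ("touching") is the spherical Delaunay graph, computed as the
convex hull of the centers' unit vectors. Temporal bins are half-open,
0-based, anchored by default at the first event date. Cell areas are
estimated by Monte-Carlo assignment of uniform region samples, so clipped
cell areas sum to the (line-integral) region area exactly.

**Binarization.** The activity field records only whether a (cell, bin)
contains at least one event. Magnitudes, fatalities and actors are kept on
the events for later stages but never enter the field: presence/absence is
far less sensitive to reporting error than counts, and it keeps the state
space of the plug-in information estimates minimal.

**Causal network.** For every ordered pair of touching cells with both
series non-constant, lag-1 transfer entropy (history length 1, log base 2)
is computed from plug-in probabilities over (x_t, x_{t+1}, y_t) counts;
for every cell, lag-1 self mutual information likewise. Finite series
inflate both plug-in estimates, so a value counts as signal only when at
least a fraction 1 − p of time-shuffled surrogates fall strictly below it;
the default cutoff is p = 1/20 with 100 shuffles (the test refuses to run
when `n_shuffles < ceil(1/p_cut)`). For TE the source series is permuted
and the target left untouched; for MI the single series is permuted. Ties
(shuffled ≥ observed) count against significance. Each directed pair draws
its own RNG stream from the master seed, so results do not depend on
evaluation order. Pairs are tested independently with no multiple-testing
correction — the per-edge cutoff is the method's tuning knob, and the
time-shuffled null network provides the global sanity check (a clustered
signal leaves only a fragmented residue at the nominal false-positive
rate). Base-2 logs only scale reported magnitudes; significance is
base-invariant.

**Avalanches and zones.** Active (cell, bin) nodes are linked when (i)
both (c, t) and (c, t+1) are active and cell c's self-MI loop is
significant, or (ii) (c, t) and (c′, t+1) are active, c′ touches c, and
the directed edge c → c′ is significant. "Sequential time" is exactly
t → t+1, matching the lag-1 statistics. Links are gated by directed edges
but components are taken on the undirected linking graph: an avalanche is
a maximal connected set of related activity, not a transmission tree. All
events in a member (cell, bin) inherit its avalanche. Components with a
single active bin are kept but flagged as singletons — they are clusters
of co-occurrence, not causal chains. A config switch
(`self_links="always"`) lays down unconditional same-cell links for
sensitivity analysis. Zones are the fixed point of merging avalanches
whose cell sets intersect (union-find, order-independent), each carrying
the fraction of zone events in which every actor appears; with multi-actor
events those fractions deliberately do not sum to 1.

**Mesoscale.** Two criteria bracket the informative scales.
Φ = (events in non-singleton avalanches)/(all events); demanding that a
"majority" of data be captured, with the uninformed midpoint of
[1/2, 1], gives Φ\* = 3/4. Counting singleton members in Φ would make it
identically 1, which is why singletons are excluded from the numerator.
Ω is the normalized mean weighted actor overlap across zones: pairwise
w_ij = Σ_actor min(f_i, f_j)/max(Σf_i, Σf_j) with f the per-zone actor
event-fractions, averaged over all ordered pairs including
self-comparisons (w_ii = 1), then rescaled by (W̄ − 1/n)/(1 − 1/n) so that
pairwise-disjoint actors give exactly 0 and identical distributions
exactly 1. This particular min-overlap form is this package's
construction; it is pinned down by the two limits and the worked two-zone
example in the test suite rather than by an external formula. A single
zone returns Ω = 1 (everything fused). The Ω cutoff is the log-midpoint
(geometric mean) of the attained positive Ω range within a realization's
scan; zeros are excluded from the endpoints, and an all-equal scan returns
the common value. The mesoscale mask per realization is
{Φ ≥ Φ\*} ∩ {Ω ≤ Ω\*}; aggregating over tessellation realizations (default
100, reducible) gives a per-scale inclusion probability, reported with 50%
and 90% contours. Scale pairs too coarse to yield at least 4 cells are
excluded from every mask.

**Scaling analysis.** Per avalanche: fatalities F (summed), reports R
(event count), duration T (inclusive bin span; optionally T·a days), sites
N (distinct cells), diameter L (max pairwise great-circle distance, km),
area A (summed Monte-Carlo cell areas, km²). Tails are fit by maximum
likelihood with a lower cutoff chosen to minimize the KS distance
(cutoff candidates capped at 100 quantiles of the unique values, tails of
at least 10 points): continuous Pareto MLE α̂ = 1 + n/Σln(x_i/x_min) for L
and A, Hurwitz-zeta discrete MLE for the integer properties F, R, T, N.
Goodness of fit is the semiparametric bootstrap (tail redrawn from the
fitted law, body resampled; p = fraction of surrogate KS ≥ observed, with
p > 0.1 read as a plausible power law); exponent errors are the SD over
nonparametric resamples with a full cutoff re-scan (default 1000,
reducible); the alternative comparison is a signed likelihood ratio
against a lognormal truncated at the same cutoff with a Vuong-normalized
p-value. The lognormal comparison uses the continuous truncated form for
discrete properties as well — an approximation adopted for simplicity.
Dynamical scaling X ~ T^γ is fit by least squares on geometrically binned
durations (8 bins per decade, bin-mean log X, at least 3 occupied bins),
using only pairs above both properties' cutoffs; binning stops the
abundant short avalanches from dominating. The exponent relation is
implemented as τ − 1 = (α − 1)/γ with γ the fitted size-vs-duration
exponent (e.g. dF/z): a change of variables on P(T) ~ T^(−α) with X = T^γ
gives P(X) ~ X^(−1−(α−1)/γ). The orientation — γ divides rather than
multiplies — is validated numerically by a synthetic
transform-and-refit oracle in the test suite and asserted as a regression
test, because the linearized notation of the relation is ambiguous.
Compatibility means |measured − predicted| ≤ 2 combined SDs, with the
prediction's error propagated from the α and γ errors.

**Interaction zones.** At fixed (a, b), the avalanche partition is
recomputed over an ensemble of tessellation seeds (default 100). Relative
to a reference event, an event's co-membership probability p is the
fraction of realizations in which it shares the reference's avalanche; the
core is the set with p = 1 (configurable to a quantile, e.g. ≥ 95%, for
robustness). Convex hulls of the events at p ≥ level (default levels 0.1,
0.5, 0.9) are computed in a Lambert azimuthal equal-area projection about
the core centroid and re-projected — convexity is projection-dependent at
continental scale, so the projection is part of the definition. Hull
families are nested by construction. Monte-Carlo noise on p has
SD ≤ ½·n_realizations^(−1/2).

## Synthetic data

`generate_synthetic_events` emulates the statistical structure the method
assumes: a homogeneous background Poisson rain (rate per km²·day over the
region × horizon) plus self-exciting offspring — each event spawns
Poisson(m) children, displaced by an isotropic Gaussian (km scale) and
delayed exponentially (day scale), discarded outside the region; m < 1
keeps clusters finite with mean size 1/(1 − m). Actor labels are per
cluster (or drawn from a shared pool), fatalities are heavy-tailed
(Zipf − 1), dates are daily. It does **not** emulate several features of
real conflict data: spatially inhomogeneous background (population-pinned
hotspots), actor movement and overlap between concurrent conflicts,
reporting bias and precision codes varying by region, or multi-actor
dyad structure. Tests passing on this generator therefore certify the
machinery (discretization, inference, chaining, scaling) under known
ground truth, not the empirical conclusions one would draw from any real
dataset.

Problem sizes in the shipped tests are desk-scale by design: the
planted-scale recovery scan uses a ~1000×1000 km region, a 22-year
horizon, ~6000 events, a 4×4 scale grid and 10 tessellation realizations;
the permutation-calibration test uses 2000 series pairs of length 500 with
200 shuffles; tail-fit tests use 10⁴–10⁵ samples with reduced bootstrap
counts. Defaults in the library (100 realizations, 1000 bootstrap
resamples) match reference practice and are config-reducible.

The co-membership test fixture (`tests/planted.py`) is more stylized: two
well-separated 3×3 site grids swept by west→east on/off activity waves,
phase-locked to the temporal bins. This construction makes the planted
truth unambiguous — each blob should always form one avalanche, the two
blobs never — while exercising exactly the linking channels the method
provides (self-loops on autocorrelated runs, directed TE along the wave).
Designing it surfaced two instructive degeneracies, documented here
deliberately: cells whose series are time-shifted copies with balanced
transition counts (e.g. period-4 fill-1/2 patterns) sit exactly on the
independence manifold of the lag-1 plug-in MI, and identical or
complementary series carry zero transfer entropy — so coherence across
cells requires genuinely staggered, redundant coupling, in synthetic
fixtures as in real data.

## Numerical choices and edge cases

- Plug-in estimates use 0·log 0 = 0; MI/TE are clamped at 0 against
  −1e−16-scale float noise; equality with direct summation over all joint
  states holds to 1e−12.
- Constant series are skipped in network inference (no lag-1 signal is
  attainable) and reported as degenerate in `shuffle_significance`.
- Assignment uses chord-metric k-d trees on unit vectors (monotone in
  great-circle distance, hence exact for nearest-neighbor queries).
- Point-in-region tests run in lon/lat space: regions crossing the
  antimeridian or containing a pole are not supported.
- The region area uses the Chamberlain–Duquette line integral on edges
  densified to ≤ 0.25°.
- Dates are truncated to days; intra-day order is not modeled (consistent
  with a = 1 day being the finest temporal scale).
- Grid/bin boundaries are half-open; an event on a bin boundary belongs to
  the later bin.
- `omega_threshold` raises on fewer than two values or no positive values.
- Avalanche and zone numbering is deterministic (sorted by earliest bin /
  lowest member id) so repeated runs are byte-identical.

## Known limitations

- Exported cell polygons (GeoJSON) are planar Voronoi polygons computed in
  a local equal-area projection and clipped to the region — an
  approximation for visualization; assignment itself is exact spherical
  nearest-center and never uses these polygons.
- Delaunay adjacency is computed from the unclipped tessellation; two
  cells whose shared boundary is clipped away by a nonconvex region are
  still treated as touching.
- History length is fixed at 1 for both information measures; no
  higher-order embedding, conditional TE, or Granger alternative is
  provided (the significance machinery accepts a callable statistic as a
  hook).
- The discrete power-law sampler for goodness-of-fit surrogates uses the
  standard continuous-approximation inverse transform.
- Φ's denominator counts events outside the region polygon against Φ;
  callers who want region-only fractions should pre-filter.
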