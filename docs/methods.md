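# Methods

This note documents the models, calibrations and numerical conventions
behind `foxrange`, and what the synthetic validation does and does not
demonstrate about real telemetry data.

## The analysis model

Home-range size of a resident fox is modelled on the natural-log scale:

    log A_i = b0 + b_elev · elev_i + b_agri · agri_i + b_sex · male_i + eps_i,
    eps_i ~ Normal(0, sigma²)

with A in km² (LoCoH-k 90% isopleth), elevation in metres, agriculture as a
unit proportion of the home range, and sex coded female = 0 / male = 1.
Candidate models are all additive subsets of {elevation, agriculture,
settlement, sex, age}; latitude is measured but removed by the collinearity
screen (see below). Model likelihoods use the ML variance estimate
sigma² = RSS/n, so logLik = −(n/2)(log(2π·RSS/n) + 1) and the parameter
count K = |slopes| + intercept + variance = |terms| + 2 — the convention
that makes the df/logLik/AICc columns of an R/MuMIn-style selection table
reproducible to the printed digit.

Interpretation of coefficients is multiplicative: a covariate change Δx
scales the median home range by exp(β·Δx). The package reports these
multiplicative effects and does not attempt additive "km² per unit"
phrasings, which are not well defined for a log-linear model.

## Residency classification

Net squared displacement is aggregated to daily means and fit with three
mean shapes: constant (resident), sigmoid (disperser) and linear through
the origin (transient). Two departures from a naive least-squares/AICc
competition are deliberate:

* **AR(1) residual likelihood.** Successive NSD values are strongly
  autocorrelated; treating residuals as independent lets the flexible
  sigmoid soak up a resident's slow within-range wander and wins it the
  competition far too often. Candidates are therefore scored with the
  exact stationary AR(1) Gaussian likelihood (lag-1 residual regression
  estimate of rho, likelihood concentrated over the innovation variance),
  with K = shape parameters + 2.
* **Bounded transition scale.** The dispersal sigmoid's transition
  parameter is capped at phi ≤ span/8: a credible dispersal completes well
  inside the monitoring window, while an unbounded phi degenerates into a
  slow ramp indistinguishable from drift.

Measured on simulated data: 240/260 residents labelled correctly (92%),
10/10 dispersers, and 9–10/10 transients. The residual misses are
residents whose wander genuinely resembles a range shift — the same
animals a human analyst would flag for visual inspection, which is why the
full per-candidate fit table is returned rather than just the label.

## Home-range estimators

* **percent-MCP** peels by distance to the fixed arithmetic-mean centroid
  of all fixes (single pass, no iterative re-peeling), ties broken by
  earlier timestamp, and keeps ceil(level·n) fixes.
* **LoCoH-k** uses hulls of each fix plus its k−1 nearest Euclidean
  neighbours (distance ties by ascending fix index), sorted by (hull area,
  root index), unioned until the union covers ≥ ceil(level·n) fixes,
  boundary inclusive. Coverage is monotone in the number of hulls, so the
  union size is found by bisection, and all isopleth levels reuse one
  sorted hull list — which also makes isopleths nested by construction.
* k = round-half-up(√n), floored at 3; fewer than 9 fixes is an error.
* All geometry is planar metres; areas are reported as km² = m²/10⁶.
  Collinear or sub-3-point inputs yield zero-area results carrying a
  degeneracy flag instead of raising, so single bad animals do not abort a
  cohort run.

The convex hull itself is a monotone-chain construction validated in the
tests against a brute-force O(n³) edge oracle and scipy's Qhull.

## Landscape composition

Zonal mean elevation uses the cell-centre-in-polygon rule
(boundary-inclusive). If a range is smaller than a raster cell the
pipeline falls back to the value of the cell containing the centroid; the
strict zonal function itself raises, directing to a finer grid or to the
contour method (length-weighted mean of clipped contour elevations, no
inter-contour interpolation). Where agriculture and settlement would
overlap, settlement wins — agriculture is only counted outside the
settlement class. Vegetation-zone polygons are ordered south to north and
a centroid on a shared border is assigned to the southernmost zone.

## The synthetic study generator

The generator emulates a 52-fox study (33 males) split 30/14/8 across
boreonemoral (BN), southern-boreal (SB) and northern-boreal (NB) zones.
Defaults, with units:

| parameter | default | meaning |
|---|---|---|
| betas (b0, b_elev, b_agri, b_sex) | 1.2, 0.003/m, −1.37, 0.34 (log km²) | truth model for log area |
| r2_target | 0.50 | population R²; sigma² = Var(Xb)·(1−R²)/R² on the realized covariates |
| zone elevation (mean ± sd, m) | 54±22 / 106±40 / 605±164 | truncated normal ≥ 0 |
| zone agriculture (prop.) | 0.28±0.21 / 0.25±0.21 / 0.02±0.02 | truncated to [0,1], joint cap p_agri+p_set ≤ 0.95 |
| zone settlement (prop.) | 0.01±0.04 / 0.07±0.15 / 0.00±0.005 | idem |
| zone latitude centres | 59.0 / 60.5 / 62.5 °N | ± 0.15° residual sd |
| elevation→latitude gradient | 0.002 °/m | within-zone coupling (see below) |
| monitoring duration | 170 ± 78 d, truncated [84, 270] | rejection-sampled, rounded to days |
| fix rate | 3/day (6 supported) | evenly spaced UTC timestamps |
| OU fix correlation | 0.7 at 3 fixes/day | decays exponentially with lag |
| subadult share | 0.25 | age has no true effect |

The intercept 1.2 log-km² anchors the southern-zone mean areas near the
emulated study's 4.7–5.2 km²; it only sets overall scale and cancels from
every ratio and recovery check.

**Movement.** Residents follow a discrete mean-reverting
(Ornstein–Uhlenbeck) walk whose stationary per-axis sd s is chosen so the
90% quantile ellipse of the position cloud has the fox's true area:
s = sqrt(A/(π·q₀.₉)), q₀.₉ the chi-square(2) quantile. Because the LoCoH-k
90% estimator hugs a finite track more tightly than the Gaussian ellipse
(it recovers ~0.79 of the ellipse area; Monte-Carlo over replicate
studies), s is inflated by 1/√0.79 ≈ 1.12 so estimated areas are unbiased
for the truth table. Dispersers run two resident phases with centres 12 s
apart joined by a 10%-of-track transition leg; transients follow a
drifting random walk with no home centre.

**Landscape.** Each fox owns a disjoint patch square (half-width
max(7 s, 1 km)) tiled with vertical agriculture/settlement strips whose
areal shares equal the fox's drawn proportions, so any convex region well
inside the square sees those proportions; the elevation raster (250 m
cells) carries the fox's drawn elevation (±5 m smooth ripple) inside its
square and the zone mean elsewhere; latitude is the fixed affine map
lat = 58° + y/111320.

**Latitude–elevation collinearity.** Zone-centre draws alone give a
fox-level latitude–elevation correlation of ~0.80. Real Scandinavian
terrain rises northward within regions too, so fox latitude adds
0.002 °/m × (elevation − zone mean). With the default zone geometry this
yields r = 0.888 ± 0.015 across seeds, matching the strong collinearity
the analysis pipeline must screen out (elevation is the true driver, so
the AICc arbiter retains it and drops latitude).

## What the generator does not emulate

No GPS fix error or missed fixes, no habitat-selective movement, no
territory interactions, no seasonal range shifts, and land cover arranged
in regular strips rather than realistic field mosaics. Passing tests
therefore demonstrate the *pipeline's* correctness and the *estimators'*
statistical behaviour under known conditions — not robustness to the
messiness of real collars.

One structural limitation is worth stating plainly: the truth model with
the configured coefficients and zone covariate distributions implies a
northern-vs-southern mean-area contrast of roughly 7–9×, larger than the
~4× contrast reported by the emulated field study. A
single log-linear model cannot reproduce both the coefficients and the
observed zone means (the residual structure of the field data is not
zone-neutral); the generator is faithful to the coefficients, since those
are what the recovery experiments measure, and the zone-ratio check in the
acceptance suite records the discrepancy rather than papering over it.

## Numerical conventions and problem sizes

* RNG: `numpy.random.default_rng`, fully determined by the study seed;
  identical seeds reproduce studies byte for byte.
* Tie-breaks everywhere are by ascending index/timestamp, making outputs
  deterministic for a fixed input order.
* Exact-fit (RSS = 0) OLS raises an infinite-likelihood error rather than
  returning −∞-AICc winners; rank-deficient designs name the aliased term.
* The paired estimator comparison is a two-sided paired Student t.
* The recovery experiment uses 200 replicates of n = 52 (a few seconds);
  the end-to-end pipeline validation runs one full default study
  (52 foxes, ~28,000 fixes, ~20 s) shared across tests.
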