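# Methods

`surveysim` is an operating model for multi-stage fisheries-independent trawl
surveys. It simulates (1) an aggregate age-structured population, (2) its
distribution over a depth-stratified spatial grid with correlation across
space, ages and years, (3) stratified-random surveys with hierarchical
length/age sub-sampling, and (4) design-based stratified estimation with
error scoring against the catchability-corrected truth. This note documents
the model, its numerical choices and its limitations.

## Population model

Cohort bookkeeping is exponential decay under total mortality Z:

    N[a, y] = N[a-1, y-1] * exp(-Z[a-1, y-1]),

with the first year filled downward by the same decay from its recruitment,
and recruitment (age-1 abundance) lognormal around a baseline with a
random-walk log deviation:

    log N[1, y] = log(mu_r) + eps_y,   eps_y ~ Normal(eps_{y-1}, sigma_r^2).

The walk is anchored at eps_0 = 0, so year-1 recruitment is centred on
log(mu_r). No plus group is modelled — extend the age vector until cohorts
are effectively empty — and no stock-recruitment relationship is implemented.

Log total mortality is a baseline plus a stationary separable 2-D AR1
Gaussian process: log Z = log(mu_Z) + delta, where delta has marginal
variance sigma_delta^2 and lag-1 correlations phi_delta_age and
phi_delta_year. The process is sampled exactly as
`sigma * L_age @ G @ L_year'` with `L` the Cholesky factors of the two AR1
correlation matrices; the *marginal*-variance convention is used (the
diagonal of the covariance is sigma_delta^2 exactly, not a conditional
innovation variance).

Growth is von Bertalanffy, `L(a) = Linf - (Linf - L0) exp(-K a)`, with
lognormal length-at-age scatter sigma_L (log scale). Length bins are
left-open/right-closed, width `length_group`, labelled by their upper edge,
spanning 0 to ten times the maximum predicted mean length. The probability
of a fish of age a falling in bin l is the difference of normal CDFs of the
log edges *centred on the log mean length at age*; the top bin's edge is
treated as infinite so each row of phi sums to one exactly for any sigma_L.
The same lognormal law (retained in the population object) later assigns
lengths to fish caught by the survey, so simulated samples and the
abundance-at-length matrix come from a single generative law.

Default parameters describe a generic long-lived demersal stock: ages 1–20,
years 1–20, mu_r = 3e7 fish, sigma_r = 0.5, mu_Z = 0.5/yr, sigma_delta = 0.2,
phi_delta_age = 0.9, phi_delta_year = 0.5, Linf = 120 cm, L0 = 5 cm,
K = 0.1/yr, sigma_L = 0.1, 3 cm bins. mu_r may be a per-year vector and mu_Z
an age x year matrix.

## Survey frame

Generated grids are regular rasters of square cells with depth varying along
x only. The depth profile is a monotone ramp from d_min to d_max with a flat
shelf of width `shelf_width` at `shelf_depth`, centred where the plain linear
ramp crosses the shelf depth, and exactly linear when the shelf width is
zero. Any monotone profile honouring (d_min, d_shelf, w_shelf, d_max) would
serve; the piecewise-linear-with-plateau form was chosen for transparency
since no downstream quantity depends on the exact curve. Divisions split the
y-axis into `n_div` equal bands; strata are depth classes between successive
`strat_breaks` (left-open/right-closed, boundary depths join the class whose
upper edge they equal), each split `strat_splits` ways along y within its
division. Stratum ids are integers ordered by (division, depth class, split).

User frames load from CSV cell tables or NetCDF rasters with layers
depth/cell/division/strat on projected km coordinates (geographic
coordinates are refused); cell area is inferred from the coordinate spacing.

## Spatial distribution

Cell shares for each (age, year) are

    eta = exp( -(d - mu_d)^2 / (2 sigma_d^2) + xi ),
    N[a, y, s] = N[a, y] * eta[a, y, s] / sum_s eta[a, y, s],

a log-scale depth parabola peaking at mu_d (200 m default, width 70 m) plus
a zero-mean Gaussian field xi with separable covariance

    sigma_xi^2 * AR1(age; phi_age) x AR1(year; phi_year) x Matern(space).

The Matern correlation uses smoothness lambda and scale
kappa = sqrt(8 lambda)/range, so correlation is ~0.14 at the range distance
(300 km default; sd 2.8, phi_age 0.5, phi_year 0.9, ages 5+ sharing one
field by default, which makes older ages school together). Sampling is exact:
Cholesky factors of the three correlation matrices applied along each axis of
an iid normal array, with a 1e-10 diagonal jitter guarding numerically
semidefinite spatial matrices. Grouped ages/years are simulated once at the
group's first index and broadcast, so grouped slices are bit-identical. The
normalization is computed after subtracting the per-(age, year) maximum of
the log shares, so extreme fields cannot overflow.

The dense Cholesky path is exact and intended for grids up to a few thousand
cells; the default 80 x 80 frame (6400 cells) works but takes minutes, and
all shipped experiments use a 20 x 20 (14 km cell) version of the same
geometry. Conservation is exact by construction: the spatial step
redistributes the cohort-model abundance, never changes it.

## Survey sampling

Per year and replicate, stratum h receives
`max(min_sets, round(A_strat,h * set_den))` sets (rounding half away from
zero), at cells drawn uniformly *with replacement* from the stratum, so
several sets can land in one cell. Catch per set and age is

    n ~ Binomial(N_avail, min(1, k * (A_trawl / A_cell) * q_a)),

where q_a is logistic in age (steepness k_q = 2, midpoint x0 = 3 by default;
a per-age table can be supplied instead, e.g. for dome-shaped selectivity),
and k is the number of co-located sets: the cell's fish are first partitioned
across the k sets by an equal-probability multinomial (N_avail is the set's
partition) and each set then tows its `A_trawl` within its `A_cell / k`
share. The k-scaling keeps the per-set expected catch equal to
`N_cell * (A_trawl/A_cell) * q_a` regardless of co-location — without it the
stratified estimator is biased low wherever `min_sets` forces several sets
into small strata — while the summed catch can still never exceed the cell
abundance. Fractional cell abundances are integerized only at this sampling
step, by stochastic rounding (floor plus a Bernoulli draw of the fractional
part, per replicate): the rounded abundance has exactly the continuous mean,
so rare ages whose cell abundances sit below one fish are sampled in
proportion to their abundance instead of being rounded away. The spatial
table itself stays continuous.
Surveys never deplete the population between years, and a `census` survey
(one set in every cell) provides the exact-recovery limit used in testing.

Sub-sampling instantiates fish only for the catch: every caught fish gets a
binned length from the growth law; up to `lengths_cap` fish per set are
measured (uniformly without replacement); of the measured fish, in
length-stratified mode up to `ages_cap` are aged per `age_length_group` cm
bin per spatial group (division, stratum or set) per year, and in random
mode up to `ages_cap` per set. Defaults: 2 sets/1000 km^2, minimum 2 sets
per stratum, 1.5 km x 0.02 km trawl, 500 lengths/set, 10 otoliths per 1 cm
bin per division, length-stratified.

## Stratified analysis

With N_h = A_strat,h / A_trawl trawlable units per stratum and per-set values
y_i (total catch; scaled length frequencies; ALK-expanded age frequencies):

    I_hat = sum_h N_h * mean_h(y),
    Var   = sum_h N_h^2 * (1 - n_h / N_h) * s_h^2 / n_h,

the classic stratified-random estimator with finite-population correction.
Zero-catch sets enter the means as zeros (required for design-unbiasedness);
a stratum with a single set raises an error rather than returning an
undefined variance. Length frequencies per set are the measured counts
scaled by n_i / m_i so they sum to the catch; age frequencies push them
through an age-length key p(age | length bin, unit) built from aged fish at
the chosen scale (division, stratum or set), always within year and
replicate. A bin with frequency but no aged fish at its unit borrows the
nearest populated bin's key (ties to the shorter bin; occurrences are
logged); a unit with frequency but no aged fish at all raises, since that
analysis scale is finer than the ageing design. Analysis length bins default
to the simulation bins ("inherit") and may be any multiple of them.

Error statistics pair estimates with the catchability-corrected truth
I = q_a N[a, y] (and its length-binned counterpart) and report ME, MAE, MSE
and RMSE pooled over years, replicates and, for the disaggregated
estimates, bins. At-length pairing uses the union of bins where either
truth or estimate is nonzero (zero-filled on the other side); at-age pairing
uses the full age vector.

## Design experiments

`expand_surveys` builds the Cartesian design grid (set density slowest);
`test_surveys` runs every design over one fixed spatial population so
designs are compared on identical truth. Each replicate's random stream is
keyed by (seed, design id, replicate id), making results bit-identical for
any n_sims/n_loops batching (a memory knob only) and any worker count.
Checkpoints are per-(design, loop) CSV files plus a JSON manifest carrying a
hash of the full configuration; `resume_test` refuses a tampered manifest,
completes missing tasks and reproduces an uninterrupted run exactly.

## Reproduction experiments and problem sizes

`surveysim.evaluation` re-creates the package's headline findings at desk
scale (the sizes are the package's own choices for single-CPU runs):

- **Unbiasedness**: default population on the 20 x 20 (14 km) grid, default
  protocol, 500 replicates; per-year mean relative error of the stratified
  total stays within 3 Monte-Carlo SEs of zero.
- **Set density vs sub-sampling**: 10-year population with mu_r = 3e6 on the
  same grid, 3 km x 0.3 km trawl (so ~10^2-fish catches make the caps bind),
  designs {0.5, 1, 2, 5}/1000 sets km^-2 x lengths_cap {25, 100}, 200
  replicates each: total RMSE falls strictly with set density, and
  quadrupling sets buys several times the at-length RMSE drop of quadrupling
  measurements.
- **ALK scale**: same population made age-clustered (no age grouping,
  Matern range 40 km, sd 2.8, phi_age 0.5), 300 replicates per protocol.
  Division-pooled length-stratified ageing with division-scale keys leaves
  significant per-age bias (|z| well above 3); concurrent set-level ageing
  (1 otolith per 3 cm bin per set) with set-scale keys is unbiased within
  Monte-Carlo error.
- **Process recovery**: the mortality AR1 parameters (0.9, 0.5), its
  variance (0.04), the recruitment increment variance (0.25), the field SD
  (2.8) and the Matern correlogram are recovered within 2% relative (0.02
  absolute for correlations) from 10^3–10^4 Monte-Carlo replicates.

The census oracle uses survival exp(-Z) = 1/2 and recruitment equal to a
power of two times the cell count, so every cell abundance is an exactly
representable integer and the exhaustive survey must reproduce the truth to
float precision — a sharp end-to-end correctness check of the whole chain.

## What the generator does and does not emulate

Populations aggregate by age class and are uniform within a cell; there is
no movement within or between survey years, no larval dispersal or spatially
varying growth, no stock-recruitment feedback, no vessel effects, no ageing
error, and tow geometry is perfectly standard. Passing tests therefore
demonstrate the statistical machinery of the survey and estimator under the
stated generating model — not robustness to the many real-world violations
of it (fine-scale schooling by length, within-survey movement, variable tow
performance), which is exactly the gap simulation testing of a *known*
population is meant to isolate.

## Numerical notes

- A single root seed feeds named substreams (recruitment, mortality, field,
  survey x design x replicate), so adding draws in one component never
  perturbs another, and batching/parallelism cannot change results.
- sigma = 0 collapses every stochastic component to its closed-form
  deterministic map (used extensively in tests).
- Degenerate inputs: single ages/years/strata work; empty strata cannot
  occur (grid construction guarantees nonempty strata); catch probability
  above 1 (trawl larger than cell) is rejected.
- Sample variances are clipped at zero to absorb ~1e-16 rounding negatives.
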