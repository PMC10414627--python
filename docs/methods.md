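# Methods

## Model overview

`mc2dose` reconstructs annual absorbed organ doses (Gy) for individuals
with known residence histories in two exposure regions: settlements along
a contaminated river (chronic ingestion of river water plus external
exposure on and near the shoreline) and villages on a fallout trace
(ingestion of contaminated foodstuffs plus external exposure to deposited
activity). Four components are evaluated separately per person, calendar
year, organ and Monte-Carlo realization: riverside internal, riverside
external, fallout-trace internal, fallout-trace external. Cumulative doses
are the prefix sums of the annual values; the annual internal dose is
obtained by differencing consecutive cumulative kernel sums, which is
nonnegative because the dose-coefficient kernels are cumulative-to-date
and nondecreasing in time since intake.

Age enters as the integer calendar-year difference τ = y − birth year;
ages 0–9 have their own intake/kernel bins and everything at age ≥ 10 uses
the adult value (11 age bins). People may live in several places within a
year; every intake and external term is duration-weighted over the
residence fractions of that year.

## Uncertainty structure

Every mean-value parameter carries multiplicative error factors, split
into

* **shared** factors — systematic, lack-of-knowledge errors common to a
  scope (whole cohort, village, household, age group, nuclide–organ cell,
  time slice, month) within one realization; they induce between-person
  dose correlation; and
* **unshared** factors — stochastic errors independent across people
  (behavioral time fractions, residence-location ratios, individual
  biokinetics, measurement noise).

The registry module encodes this as one record per parameter family with a
distribution (normal, lognormal, uniform, log-uniform, or a tabulated
empirical quantile grid sampled by inverse CDF), a sharing scope, and
index dimensions whose cardinality product gives the scalar parameter
count. At the default dimensioning (42 riverside settlements, 84
fallout-trace villages, 11 nuclides — 6 on the trace — 23 organs, 53
time slices, 11 age groups, 15 months, 20-move limit) the registry totals
1,436 shared and 422 unshared scalars. The dose-coefficient error family
appears on both sides (253 shared + 253 unshared cells). The individual
intake modifier ξ is deliberately *not* a registry row: it is carried on
the individual (see below). Where a family is quoted with two candidate
shapes for its shared error, both are stored (`spec` and
`alt_shared_spec`) and the configuration selects per nuclide class; the
default uses the lognormal form.

Normal multiplier distributions are truncated below at 0 (doses cannot be
negative). In the Latin-hypercube path the truncation is applied through
the truncated-normal inverse CDF, which keeps the stratification exact;
plain Monte-Carlo draws resample instead. For the distributions used
(sd ≤ 0.25 around a mean of 1) the truncated mass is below 4 standard
deviations — numerically negligible either way.

## Two-step sampling

**Step 1 (shared).** For each realization, one vector of all shared
factors is drawn by Latin hypercube sampling: for every shared scalar the
n realizations occupy the n equiprobable strata of its distribution
exactly once (stratum permutation plus an in-stratum uniform jitter,
mapped through the inverse CDF). Stratum permutations are independent
across scalars; no cross-parameter correlation is induced, since the
registry declares none. A run with fewer realizations than shared
parameters warns (or errors under `strict`) because hypercube coverage
then cannot give one realization per parameter.

**Step 2 (unshared).** Each person's evaluation is perturbed with
unshared factors drawn from generators keyed by (master seed, individual
id, realization index, parameter family, index). The keyed scheme makes
every (person, realization) pair reproducible in isolation and
independent of cohort ordering. Move-indexed factors are drawn once per
residence record; age-indexed factors once per age bin; the
dose-coefficient error once per (nuclide, organ) per person — a
biokinetic trait, constant over the person's years rather than redrawn
annually.

**Autocorrelation.** Families marked as autocorrelated across age (dose
coefficients, air-to-organ factors) or calendar year (shoreline dose
rate) are counted and LHS-sampled as one scalar per family cell; the
per-age (or per-year) values are expanded from that anchor as a
stationary AR(1) sequence in normal scores (the anchor is the first
element; innovations come from a deterministic stream keyed by the table
seed), mapped back through the marginal distribution. The default AR(1)
coefficient is ρ = 0.8, chosen as a strong but not degenerate persistence
since no coefficient is specified anywhere; it is configurable per scope.
ρ → 1 reproduces a single shared multiplier across the index; ρ = 0 gives
independent bins.

**Behavioral fractions.** T1 (riverbank) and T3 (indoors) are the two
independent unshared behavioral parameters, each a lognormal multiplier
(GSD 2.7) on an age-dependent mean curve; T2 = 1 − T1 − T3 is derived
after perturbation, and if T1 + T3 > 1 both are rescaled proportionally
so T2 = 0.

## Individualization (IMR/HSR)

A person with ⁹⁰Sr body-burden measurements carries a measured-to-model
ratio (IMR); their intake is scaled by ξ = 1/IMR with an unshared
lognormal error whose log-sd shrinks as 1/√(number of measurements) from
a baseline GSD of 1.5 — a deliberately simple declining-error rule, since
only the direction (more measurements, less error) is specified.
Unmeasured members of a household with measured members use the household
average of member IMRs (HSR, arithmetic average); the HSR error draw is
keyed by household, i.e. shared within the household, shrinking with the
number of measured members. People with neither keep ξ = 1 and the full
village-level shared intake error.

## Summaries

Per-person statistics over realizations: arithmetic mean and CV on the
natural scale, geometric mean and GSD on the log scale, using population
moments (ddof = 0). Zero realizations are excluded from the log-scale
statistics with the zero fraction reported (doses are products of
positive factors; zeros only arise from a zero base dose); an all-zero
vector reports GM = 0, GSD = 1 with a flag. Population tables summarise
the distribution of the per-person statistics with mean, CV and the
5/25/50/75/95 percentiles plus the maximum; percentiles use linear
interpolation between order statistics (numpy's default, type 7), stated
here because the table layout alone does not pin a rule. The
`cv_from_gsd`/`gsd_from_cv` pair converts under exact lognormality
(CV = √(exp(ln²GSD) − 1)); empirical GSD/CV pairs from ensembles are
independently estimated statistics and need not satisfy this identity.

The realization-ratio CDF diagnostic plots, for selected realizations,
the empirical CDF over people of (dose in that realization)/(person's
mean dose). Purely unshared error makes the curves coincide; shared error
translates whole curves horizontally — the realization's systematic
offset.

## Distribution classification

Each person's total-dose realization vector is fitted by maximum
likelihood to six candidate families — lognormal, three-parameter
(scaled) beta on (0, c) with c pinned just above the sample maximum, GEV,
gamma (origin fixed at 0), generalized logistic (type I), Weibull (origin
fixed at 0) — and tested with a one-sample Kolmogorov–Smirnov statistic
against the fitted CDF. The label is the candidate with the largest
p-value above 0.05; if all fall below 0.05 the label is "none". A
non-convergent fit is recorded with p = 0 and flagged, never fatal.

Because parameters are estimated from the tested sample, the naive
asymptotic K-S p-value is anti-conservative (inflated). Both p-values are
offered: a parametric bootstrap (fit → simulate → refit, default 199
resamples), which is well calibrated — fitting the generating family to
its own samples rejects at the nominal 5% rate — and the asymptotic
value. The bootstrap's calibration has a structural consequence for the
labelling rule: a calibrated p is uniform under the true family, so about
5% of genuinely lognormal samples fall below the 0.05 gate and drain into
"none" or a rival label. Batch classification therefore defaults to the
asymptotic p, which almost never rejects the true family and reproduces
the intended behavior of the selection rule; the bootstrap is the right
choice when the p-value itself (not the label) is the object of
inference.

## Synthetic data

The generator emits complete engine-ready bundles: settlement tables
(riverside settlements with exponential distance decay of shoreline dose
rate, intake ratio and residence-to-riverbank ratio; trace villages with
log-uniform ⁹⁰Sr depositions spanning 3.7–17,800 kBq/m², the most
contaminated evacuated soonest), a front-loaded reference intake series
(≥ 95% of total intake in the first four slices; a "short" variant
truncates mid-series), cumulative dose-coefficient kernels (bone-seeking
strontium accrues marrow dose over decades; short-lived nuclides and soft
tissues saturate within 1–2 years; children receive more per unit intake,
monotonically down to the adult value), behavioral curves, and a cohort
with households, chronological residence histories (≤ 20 records,
evacuees move on evacuation dates) and configurable measurement
availability with household propagation.

The exact functional shapes (exponential decays, saturating
exponentials, dose magnitudes) are arbitrary smooth stand-ins: they give
the engine the *structure* it assumes — nonnegativity, monotone
cumulative kernels, front-loaded intake, realistic dimensioning — but not
the real release history, geography or demographics. Passing tests
therefore demonstrate the correctness of the propagation machinery and
its statistical guarantees (stratification, sharing scopes, closure,
correlation structure), not agreement with any real cohort's dose
distributions, which would require the original parameter databases.

## Numerical choices

* Dose arrays are float64; component additivity and oracle equivalence
  hold to 1e-12 relative.
* Dose-coefficient lags beyond the table horizon extrapolate flat (the
  cumulative dose stops accruing) with a one-time warning per kernel.
* Intake years with zero reference intake and people not yet born
  contribute exactly 0.
* The monthly normalized fallout dose-rate table (15 months, each month
  with its own shared multiplier) is aggregated to calendar years by the
  deposition date; later years use a deterministic annual tail.
* All randomness flows from one master seed; the shared stage, the
  AR(1) innovations and every unshared stream are derived from it by
  fixed integer key paths (no global state, no order dependence).

## Problem sizes

The test suite exercises the full default registry (1,436 + 422 scalars)
for sampling guarantees, 1,500-realization runs on one- and
two-person scenarios for closure and correlation checks, and a
200-person, 50-realization, 3-organ synthetic cohort for the end-to-end
pipeline. `scripts/acceptance.py` uses a 200-person cohort at 300
realizations for the summary and classification metrics. These sizes were
chosen to make every statistical check sharp (stratification is exact at
any n; GSD estimates at n = 1500 carry ≈ 1–2% sampling error) while a
full run remains a desk-scale computation.

## Limitations

* The engine evaluates the organs present in the input bundle; the full
  23-organ list is available but synthetic defaults use three
  (stomach, marrow, thyroid).
* Sub-annual dose dynamics are out of scope: the year is the atomic time
  step, and in-year moves are handled by duration weighting only.
* No cross-parameter rank correlation is induced in the hypercube
  (none is declared in the registry); correlated LHS would be needed if
  such dependencies were ever specified.
* The bootstrap p-value refits every resample, which is accurate but
  slow for the three-parameter families; batch classification uses the
  asymptotic p by default.
* Radionuclide transport modelling (the physics that would produce the
  shoreline dose-rate and intake-ratio tables) is outside the package;
  those tables are inputs.
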