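# Methods

`swedge` is a design and power engine for stepped wedge cluster randomised
trials of physical-activity interventions in primary schools.  This note
records the models it implements, the defaults it ships, and the choices
made where the design was genuinely open.

## Setting and notation

The target study randomises schools to one of five sequences over a single
school year of six terms, with a baseline measurement occasion at the end
of the previous school year.  The outcome is accelerometer-measured average
weekday minutes of moderate-to-vigorous physical activity (MVPA) per pupil.
Each sequence crosses from control to intervention at a different term; the
crossover term is an unmeasured one-term *implementation period* during
which the intervention is embedded.  Because of the implementation periods
and a cap on data-collection burden, the designs of interest are
*incomplete*: each school contributes a baseline measurement plus three
in-year measurements rather than being measured at every term.

## Data-generating model

For pupil *j* of school *i* measured at period *t*,

    y_ijt = mu + f(time_t) + delta * treated_it + u_i + v_it + w_ij + e_ijt

with independent Gaussian random effects: school `u_i ~ N(0, sigma_s^2)`,
school-period `v_it ~ N(0, sigma_st^2)`, pupil `w_ij ~ N(0, sigma_p^2)`
(cohort designs; a pupil keeps one draw across occasions) and residual
`e_ijt ~ N(0, sigma_e^2)`.  The four variances are parameterised by the
total SD together with three correlations:

    sigma_s^2  = CAC * ICC * SD^2         sigma_st^2 = (1-CAC) * ICC * SD^2
    sigma_p^2  = IAC * (1-ICC) * SD^2     sigma_e^2  = (1-IAC) * (1-ICC) * SD^2

Study defaults: SD 23 min, ICC 0.08, CAC 0.75, IAC 0.45, giving components
(31.74, 10.58, 219.006, 267.674) min².  The intervention effect delta
defaults to 5 min; the baseline mean is 100 min (arbitrary — every reported
quantity is a contrast, so the location cancels).  For cross-sectional
designs pupils are never remeasured and sigma_p^2 is folded into the
residual.

`f(time)` is an optional additive trend.  The seasonal trend is a periodic
cubic spline through 12 monthly knot heights (packaged shape: single summer
peak, winter trough), rotated to the requested peak month and rescaled so
its peak-to-trough range equals the requested amplitude exactly (default
4 min between winter and summer).  A linear secular trend (default 0,
typical UK value ~2 min/year) can be added instead or as well.

Calendar: period 0 is the baseline occasion (June of the previous school
year); Terms 1–6 carry mid-term calendar positions (Oct, late Nov, late
Jan, Mar, late Apr, Jun), i.e. months −3, 1, 2.5, 4.5, 6, 7.5, 9 from the
September study start.  Seasonality is evaluated on the cyclic
month-of-year axis; secular trends on elapsed months.

## Candidate designs and the constraint set

Designs are sequence-by-period matrices of cell states (measured/unmeasured
control, implementation, measured/unmeasured intervention).  The default
`ConstraintSet` encodes the school-year study: five sequences implementing
in Terms 1–5 (one each), a common measured baseline, exactly three in-year
measurements per sequence, the first post-implementation term always
measured, no more than two measurements in consecutive terms, and
measurements spread across the year — exactly one in each third of the
year (Terms 1–2, 3–4, 5–6).

The spread rule deserves a note.  The first four rules alone admit 4,500
configurations.  Adding the one-per-third spread rule — data collection
spread over the year is one of the stated scheduling considerations —
yields per-sequence schedule counts of 4, 2, 4, 2, 4 and hence exactly
**256** configurations, and makes the exactly-three and consecutive-terms
rules automatically satisfied.  We adopt this as the default reading; every
rule is individually toggleable, and an infeasible combination returns an
empty list plus a report of which rule eliminated the last candidates.

## Analysis model and estimation

The analysis mirrors the generating model: fixed effects are an intercept,
a time adjustment and the treatment indicator; random intercepts are
school, school-period and (cohort designs) pupil.  The treatment effect is
tested two-sided against a standard normal reference (Wald).  A normal
rather than small-sample reference is used; at 15–20 clusters this is
mildly anti-conservative, which the type-I-error calibration test bounds
empirically.

Three time adjustments are available:

* `categorical_period` — one indicator per period (reference dropped);
* `fixed_df_spline` — cubic B-spline of fixed rank;
* `penalized_thin_plate` — fixed linear term plus thin-plate smooth
  deviations whose coefficients form a zero-mean random effect with a
  REML-estimated variance (the mixed-model form of penalized smoothing).

The default picks `categorical_period` when a design has six or fewer
distinct calendar positions (the textbook discrete-time analysis for the
complete comparator, and the form under which simulated and closed-form
power agree by construction) and `penalized_thin_plate` for school-year
designs with seven positions spanning a full seasonal cycle.  The penalized
default matters: with a full-rank time adjustment, incomplete designs pay a
large precision penalty for estimating seven free period effects from four
occasions per school, and no candidate design approaches the power levels
that make these designs worth using.  Letting the data choose the
smoothness restores that power (the adjustment shrinks towards linear when
there is no trend and spends effective degrees of freedom only when a
trend is present), at the cost of slightly anti-conservative standard
errors, as is usual for plug-in smoothing.  Percentage bias under
seasonality is monitored alongside power throughout; the design sweep
reports both.

Estimation is REML.  The solver profiles out the residual variance and
maximises over log variance ratios (Nelder-Mead); each school's likelihood
contribution is reduced with the Woodbury identity to a small Cholesky
factorisation, schools with equal block shapes are batched, and the global
smooth component adds a second Woodbury layer.  A fit takes milliseconds,
which keeps 1,000-replicate power runs around a minute.  The same model
fitted with `statsmodels` MixedLM is retained as an independent
cross-check backend and the two are asserted to agree in the test suite.
Variance estimates on the zero boundary (common at 15 clusters) are
legitimate REML solutions and are kept, flagged as `singular`; only
optimizer failures are excluded from power summaries, with the exclusion
fraction reported and a 2% validation cap.

## Cohort schemes

Pupil participation follows one of three schemes per school (eligible year
group of e.g. 30): cross-sectional (fresh pupils each occasion), closed
cohort (one recruited set at every occasion) and a closed-population open
cohort.  The open scheme draws the ever-participating subset once
(recruitment rate) and makes each recruited pupil present at each measured
occasion independently with the retention probability, so that
P(present at t+1 | present at t) = retention and the expected per-occasion
participation is recruitment x retention of the eligible group.  With the
default expected-count sampling the recruited-set size and per-occasion
head counts are fixed at rounded expectations, reproducing the reference
rate mappings exactly (58% -> 10/30, 71% -> 15/30, 82% -> 20/30,
91% -> 25/30); Bernoulli sampling is available for sensitivity analyses.
Churn is 1 − retention.  Retention is constant over the year; declining
retention is not modelled.

## Closed-form power and the CRCT comparator

For shortlisting, treatment-effect variance is computed by GLS on each
cluster's measured cluster-period means with covariance
`diag = sigma_s^2 + sigma_st^2 + (sigma_p^2 + sigma_e^2)/n` and
`off-diag = sigma_s^2 + overlap * sigma_p^2 / n`, where `overlap` is 1
(closed), the retention rate (open; the expected shared-pupil fraction of
the independence mechanism) or 0 (cross-sectional).  Unmeasured cells are
deleted, fixed effects are categorical periods plus treatment, and power is
`Phi(|delta|/SE - z_{1-alpha/2})`.  With the study parameters this gives
85.2% power for the complete five-step design at 15 schools, and
`required_clusters` returns 15 for an 85% target — the anchor the
simulation engine is checked against.  A baseline-adjusted two-arm parallel
cluster-RCT comparator uses the design effect `1 + (n-1) * ICC_adj` with a
normal approximation; the baseline-adjustment convention (how much residual
variance adjustment removes) is deliberately left to the caller via the
adjusted ICC, because no single convention is canonical.

## Engine, seeding and scale

`run_power` draws each replicate from a child `SeedSequence` keyed by
(master seed, design pattern key, replicate index), so summaries are
byte-identical for any worker count and designs can be added to a sweep
without disturbing each other's streams.  Summaries report power, mean
estimate, percentage and absolute bias, mean standard error, the
Monte-Carlo SE of power and exclusion counts.  `sweep_designs` runs every
design under trend-off and trend-on settings; `shortlist` applies the
two-stage selection (high power / low SE without trend, then lowest
absolute seasonal bias) with logistics tie-breaks (peak schools per term,
consecutive measurements).

Replicate counts are configurable; the packaged scenarios and the test
suite use 600–2,000 replicates, which bound power to roughly ±1–2
Monte-Carlo SE and keep full runs to a few minutes, while 10,000+ replicate
runs are available through the same interface.  The packaged
`final_design_synthetic.csv` is the design our own pipeline selects from
the 256 candidates (analytic top-48 band, then seasonal-bias ranking at
reduced replicates, then logistics); it is a synthetic reconstruction of
the selection procedure's outcome, not a transcription of any external
artefact, as its header states.

## What the generator does and does not emulate

Simulated data are Gaussian with exactly the specified correlation
structure, balanced eligible groups, constant rates over the year and no
measurement-level missingness beyond the cohort scheme.  Real accelerometer
outcomes are skewed, wear-time censored and cluster-size variable; passing
tests therefore demonstrate that the machinery is correct and calibrated
under its stated model, not that any particular school trial will achieve
the nominal power.  Class-level clustering within schools is deliberately
out of scope.

## Numerical choices

Variance-component identities are exact to 1e-9 relative; recovery tests
use fixed seeds with ±0.02 tolerances at large n.  REML optimisation runs
on log ratios clipped to [-12, 8] (ratios below ~6e-6 are effective
zeros); Nelder-Mead tolerances are 1e-4 (parameters) and 1e-7 (objective).
Deterministic orderings break ties lexicographically on the encoded cell
pattern.  Degenerate inputs (constant treatment, empty datasets, designs
without a control/intervention contrast) raise structured errors rather
than returning numbers.
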