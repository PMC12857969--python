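# Methods

## Observation construction

A record is one shelter stay: intake date, outcome date (blank while the
animal is in care), intake/outcome type codes, size category, date of birth.
Dates are whole calendar days; all arithmetic is in integer days.  LOS counts
both endpoints, so a same-day intake and outcome is LOS 1 — the animal
consumed a day of care.

For a period `[start, end]` (inclusive) the ExitLOS slice includes every
record with `intake <= end` and (no outcome, or `outcome >= start`); an
animal whose outcome falls on the period's first day therefore belongs to the
period.  Entry time is `t0 = max(0, start - intake)` in days (no `+1`), and
risk-set membership at integer day `t` is `t0 < t <= T`.  Under this
convention an animal taken in the day before the period that exits on the
period's first day is observable at `t = 2` with `t0 = 1` — the minimum
possible truncated stay is 2, which is what the period-boundary bookkeeping
requires.  Records with no outcome are residents through the data-extract
date; a period that extends beyond a supplied extract date is refused rather
than silently censored, since residency beyond the extract is unknown.

Stays are capped at `cap = 550` days by administrative censoring: an exit
time beyond the cap becomes a censoring at the cap, and an observation whose
entire in-period window lies beyond the cap (`t0 >= cap`) is dropped with a
warning.  Restricted means up to the cap are unaffected by the choice between
"censor at cap" and "truncate value at cap" semantics.

Three bookkeeping identities hold for any contiguous period partition and are
exposed as a diagnostic report: non-truncated observations = in-period
intakes; non-censored observations = in-period outcomes; censored
observations of period k = truncated observations of period k+1 (both count
residents at the shared boundary).  The report checks them on *uncapped*
observations: the cap can drop a later-period truncated observation whose
censored counterpart in the earlier period is retained, which would break the
pairing even though the residency logic is sound.

A consequence worth stating: stacking the observations of contiguous
sub-periods reproduces the unified-period KM fit *exactly* (curve and
Greenwood variance).  A boundary-crossing resident contributes a censored
observation `(t0, c]` and a truncated one `(c, T]` whose risk coverage
concatenates to the unified `(t0, T]`, with the same events — so every
`(n_j, d_j)` pair is identical.  The acceptance suite verifies this to 1e-12
on 200 random simulated datasets.

## Record hygiene

Outcome types `DELETE DUP, FOUND EXP, HOME EXP, LOST EXP, SURG SCHED, SURG
WAIT` and intake types `DISPO REQ, EUTH REQ, WILD` are dropped by default —
they are bookkeeping artifacts, not live admissions.  Rows with unparseable
dates or an outcome before intake are rejected into a sidecar report.  Age is
the ceiling of the calendar years from birth to intake, floored at 1 and
capped at 15 (old-age cells are sparse); an exact anniversary is not rounded
up.  Missing dates of birth give an unknown age, kept in unstratified
analyses and dropped (with a warning) from age-stratified fits.  Animals
sized PUPPY but older than 1 year are reclassified MED; unknown-age puppies
keep the PUPPY label.  When a species column is present, a configurable
species filter (default dogs) runs before everything else.  `animal_id` is
not required unique: each (intake, outcome) pair is an independent stay.

## Kaplan-Meier stack

The product-limit curve uses delayed-entry risk sets computed by sorted
binary search (`#{entry < t} - #{exit < t}`), so fits are `O(n log n)`.
Greenwood's variance `S(t)^2 sum d_j / (n_j (n_j - d_j))` backs all standard
errors; the variance is set to 0 once the curve is exhausted (`S = 0`), and
an empty risk set strictly between the first and last event times triggers a
warning (the product skips the gap; the curve is unidentified across it).

Confidence bands default to the complementary-log-log (exponential
Greenwood) transform — the transformation-respecting band that standard
survival software produces by default — with the plain linear band available
for teaching and cross-checks.  Cloglog bands are undefined (NaN) where `S`
is exactly 0 or 1.

The restricted mean is the exact area under the integer-day step curve,
`sum_{t=0}^{tau-1} S(t)`; with no truncation or censoring it equals the
arithmetic mean of capped stays.  Its standard error uses the Greenwood
decomposition `SE^2 = sum_j A_j^2 d_j / (n_j (n_j - d_j))` with `A_j` the
area under `S` from `t_j` to `tau`.  Beyond the last observed time the curve
extends flat to `tau`; a warning reports when more than 5% of the mass is
extrapolated.  Percentiles use right-continuous inversion on the day grid
(`min t : S(t) <= 1 - p`), with confidence limits from inverting the band:
the lower band crosses first (lower time limit), the upper band last.  The
median is available but de-emphasized — it falls in the rapid initial drop
of shelter stay curves, where the 90th percentile is the informative tail
summary.

## Cox stack

The partial likelihood uses the same delayed-entry risk sets, with Efron tie
handling by default (integer-day stays tie heavily; Breslow is available).
Risk-set sums are suffix sums over exit- and entry-sorted orders, so each
Newton-Raphson iteration is `O(n log n + k p^2)`.  Optimisation starts at
beta = 0 with step-halving on any likelihood decrease; convergence is a
log-likelihood change below 1e-9 (max 100 iterations).  Non-finite
likelihoods force halving; a coefficient passing |beta| > 30 or a linear
predictor beyond ±200 raises a separation error naming the covariate.  The
covariance is the inverse observed information at the optimum.

Stratified fits give each stratum (e.g., each size x age cell) its own
Breslow baseline cumulative hazard `H0(t) = sum_{t_j <= t} d_j / sum_{R(t_j)}
exp(x beta)` while sharing the coefficient vector; strata without events are
excluded with a warning.  The score test at beta = 0 for a binary
later-period indicator is the primary two-period comparison; with untied,
untruncated groups its square equals the log-rank chi-square exactly, and the
sign convention makes positive z mean faster outcomes in the later period.

Diagnostics: Schoenfeld residuals subtract the Efron-adjusted risk-set mean
covariate (averaged over the tie order, consistent with the fit); scaled
residuals follow Grambsch-Therneau, `r* = beta + d V^-1 r`.  The
proportionality test regresses scaled residuals on a transformed event time
(identity by default; log, rank, and KM transforms available — reference
implementations disagree on both the transform and, since 2019, the exact
statistic; this package implements the classic Grambsch-Therneau
approximation, which matches lifelines and pre-2019 R `survival`).
Martingale residuals subtract the accumulated baseline hazard over the
observation's own window, `H0(T) - H0(t0)`, which is the delayed-entry
adjustment; deviance residuals are the usual normalisation, reported with
the fraction outside ±2.  Log-cumulative-hazard curves use Nelson-Aalen with
delayed entry, plotted against log time; proportional hazards make them
parallel with vertical offset ≈ log HR.

## Comparisons

Klein's fixed-time-point test standardises the transformed curve difference
at each day, `z(t) = (g(S_A) - g(S_B)) / sqrt(v_A + v_B)` with the cloglog
transform by default (the recommended choice over the naive difference; the
linear version reduces to the naive z).  It extends the confidence bands — an
accessible way to localise where two curves separate — and is not the primary
test; the maximal contiguous sub-alpha run is reported along with isolated
sub-alpha points outside it (earliest run wins ties; all runs are surfaced).

Period scans run the score test over adjacent or year-over-year pairs, each
labelled by the later period and treating periods as independent (within-
animal correlation across boundaries is deliberately ignored — a simplifying
approximation).  Instead of a false-discovery-rate correction, an exact
one-sided binomial meta-test asks whether the number of nominally significant
pairs exceeds what 5%-level tests would produce by chance.

Little's law converts mean stay to expected steady-state residents:
`residents = round(monthly_intakes / 30 x mean_los)`.  Thirty-day months are
the convention that makes published resident-count figures reproduce exactly.
Staffing: with one attendant per 18-20 animals, a resident-count change of
`delta` needs between `delta/20` and `delta/18` attendants daily; each
endpoint is floored to whole attendants (73 residents -> 3-4 attendants).

## Synthetic data generator

The generator emulates the statistical structure the analyses assume — not
shelter behaviour.  Per calendar day, intakes are Poisson (default 13/day,
the scale of a large municipal shelter at roughly 390 dogs/month).  Each
animal draws a size and an age from categorical distributions shaped like a
large shelter's intake mix.  Stays evolve day by day: on stay day `t` the
exit probability is `1 - (1 - h0(t))^exp(eta)` with `eta` the sum of the
size and age log hazards and the calendar regime multiplier *of the current
calendar day*.  This complementary-log-log link makes the configured `eta`
exactly the grouped continuous-time log hazard ratio, and an animal whose
stay straddles a regime change experiences both regimes — precisely the
structure that makes truncation/censoring-based period slicing meaningful.
Animals still in care at the simulation end have blank outcomes; a small
fraction of rows (2%) receives drop-listed intake/outcome type codes to
exercise the filters.  Everything is reproducible from the config seed.

The default baseline hazard is a two-component geometric mixture (escape
probabilities 0.18 and 0.02, weights 0.85/0.15): median stay ~5 days,
baseline mean ~12 days, and a 90th-percentile-to-median ratio well above the
~3.3 a single geometric yields — the heavy-tailed shape of real shelter
stay distributions, where most animals leave quickly and operational stress
accumulates in the tail.  What the generator does *not* model: kennel
capacity feedback, outcome-type taxonomy beyond filter exercising, seasonal
intake cycles, within-animal correlation of repeated stays, or the joint
size x age distribution (the margins are independent).  Tests passing on
this generator therefore validate the estimation machinery, not any claim
about a particular shelter's dynamics.

## Parameter-recovery study design

The recovery experiment simulates a warmup, a referent period A, and a
period B whose calendar regime multiplies the exit hazard by a known ratio
(0.8 by default), at ~48 intakes/day over 180-day periods — roughly nine
thousand observations per period.  Each replicate runs the full pipeline:
filters, age derivation, size reclassification, two-period ExitLOS slicing,
Cox fit with a later-period indicator, score test.

The recovery configuration sets the individual size/age log hazards to zero.
Hazard ratios are not collapsible: with individual-level heterogeneity the
*marginal* two-group hazard ratio is attenuated relative to the conditional
one (measured here at about 0.02 on the log scale under the default
heterogeneity), while the size/age-stratified fit recovers the conditional
effect either way.  A parameter-recovery study needs an unambiguous truth,
so the homogeneous population is the right design; the
stratified-versus-unstratified contrast under heterogeneity is checked
separately and mirrors the empirical pattern that a stable covariate mix
leaves the two estimates close.  At these conditions, 200 replicates give a
mean recovered coefficient within 0.002 of log 0.8 (replicate SD ~0.016)
and 95% Wald coverage at its nominal rate.

## Problem sizes and numerical choices

Simulation-backed test suites use: 200 random small datasets for the exact
stacking equivalence; 50 for the boundary identities; 50 random small
instances (20-80 subjects, heavy ties, delayed entry) for the
reference-implementation equivalence of KM and Cox at 1e-6; 200 replicates
for the hazard-ratio recovery; 20 reruns of an 8-quarter stationary scan and
200 replicates of a 1000-subject proportional-hazards simulation for null
calibration.  These sizes put Monte-Carlo error comfortably inside the
asserted bands while keeping the default test run short.

Ties between equal-length significant runs go to the earliest.  Percentile
and band inversions treat NaN band values as "not yet crossed".  The
geometric benchmark (90th percentile / median -> ln 0.1 / ln 0.5 ≈ 3.32 as
the escape probability shrinks) is computed through the percentile machinery
on a fitted curve of inverse-CDF quantile stays, not from the closed form.

## Known limitations

No time-varying coefficients or accelerated-failure-time models; no
clustered standard errors for repeated stays of the same animal; no
false-discovery-rate machinery (the binomial meta-test is the deliberate
alternative); the proportionality test is the classic approximation, not the
post-2019 exact score version; HistLOS and ExitLOS converge as periods grow
long relative to stays, so the distinction matters most at monthly-to-
quarterly resolution.
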