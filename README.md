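# shelterlos

Calendar-period length-of-stay (LOS) analytics for animal shelters, built on
left-truncated, right-censored time-to-event methods.

## The problem

Shelters track how long animals stay in care, because LOS drives the resident
count, staffing needs, crowding, and welfare.  The metric shelters and their
database vendors actually compute — here called **HistLOS** — averages the
intake-to-outcome stay of the animals whose stay *ended* in the reporting
period.  Animals still in care contribute nothing.  The result is perverse for
period comparisons: while long-stay residents accumulate, the metric stays
flat; when they finally leave, the departure month is penalised with a *rise*
in "average LOS", exactly when the shelter is emptying out.

**ExitLOS** is the corrected computation.  Every animal in care for any
fraction of a calendar period contributes one observation:

| stay vs. period | treatment |
| --- | --- |
| enters and leaves inside | fully observed stay |
| already resident at period start | left-truncated: enters the risk set at its elapsed stay `t0` (time still counts from intake) |
| still resident at period end | right-censored at its elapsed stay |
| resident throughout | both |

With risk sets `R(t) = {i : t0_i < t <= T_i}` the Kaplan-Meier (KM)
product-limit estimator gives each period's *stay curve*
`S(t) = prod_{t_j <= t} (1 - d_j / n_j)` — the fraction of animals still in
care after `t` days — and a Cox proportional-hazards regression with a
later-period indicator tests whether two periods' exit hazards differ.  A
same-day intake and outcome counts as LOS 1; stays are integer days capped at
550 (administrative censoring), and "mean LOS" is the restricted mean
`sum_{t=0}^{tau-1} S(t)` up to that cap.

The KM/Cox machinery (Greenwood variances, complementary-log-log confidence
bands, restricted means with standard errors, stay percentiles, Efron tie
handling, Breslow baselines, score tests, Schoenfeld/deviance residuals, the
proportionality slope test) is implemented from scratch in numpy and
cross-checked against independent references in the test suite.  A synthetic
shelter simulator (daily Poisson intakes, heavy-tailed discrete
proportional-hazards stays, piecewise calendar hazard regimes) provides ground
truth for every stage.

## Worked example

Simulate a shelter that accumulates long-stay residents for nine months
(slow exits), then transfers them out in a one-month wave — the situation
that most badly misleads the traditional metric:

```python
from shelterlos.simulate import SimulationConfig, simulate_records, write_records_csv

cfg = SimulationConfig(
    start_date="2023-01-01", end_date="2023-10-31", daily_intake_rate=15.0,
    period_log_hazards=(("2023-01-01", -0.7), ("2023-10-01", 1.8)), seed=31,
)
write_records_csv(simulate_records(cfg), "outflux.csv")
```

Compare September to October with each computation:

```
$ shelterlos compare --input outflux.csv --period-a 2023-09-01 2023-09-30 \
      --period-b 2023-10-01 2023-10-31 --mode histlos --outdir out
label    n  mean  mean_se  mean_lower  mean_upper   p90  p90_lower  p90_upper
23-09  427  30.6      2.4        25.9        35.3  94.0       72.0      120.0
23-10 1033  51.8      2.2        47.5        56.2 173.0      153.0      184.0
Cox score z = -3.5, P = 0.0004

$ shelterlos compare ... --mode exitlos --outdir out
label    n  mean  mean_se  mean_lower  mean_upper   p90  p90_lower  p90_upper
23-09 1030  54.2      5.6        43.2        65.2 149.0      110.0      189.0
23-10 1072   1.6      0.1         1.5         1.7   3.0        3.0        3.0
Cox score z = 42.3, P = 0
```

HistLOS (first block) sees only the departing long-stayers and reports mean
LOS *rising* from 30.6 to 51.8 days — significantly (negative z: slower
outcomes).  ExitLOS (second block) accounts for every resident and shows what
actually happened: the October stay distribution collapsed (mean 54.2 to 1.6
days, strongly positive z: faster outcomes).  The two computations disagree
not just in size but in direction.

The same CLI provides `slice` (observation tables and the period-boundary
bookkeeping report), `km` (per-period restricted means and 90th stay
percentiles with band-inverted confidence intervals), `scan` (Cox score tests
over consecutive or year-over-year periods with an exact binomial meta-test),
`cox` (two-period regression with and without size/age strata, plus
proportionality and residual diagnostics), and `simulate`.  Everything is also
available as a library: `KaplanMeier` and `CoxPH` are sklearn-style estimators,
and each CLI step is a thin wrapper over `build_exitlos`, `fit_km`, `fit_cox`,
`score_test`, `klein_pointwise`, `consecutive_period_scan`, and friends.

Operational translation via Little's law: a mean stay of 20.8 days at 387
intakes/month implies `387 / 30 x 20.8 ≈ 268` residents in steady state;
at 15.1 days it would be 195.  The difference of 73 residents is 3-4 extra
animal-care attendants every day (at 18-20 animals per attendant):

```python
>>> from shelterlos import littles_law_residents, staffing_delta
>>> littles_law_residents(20.8, 387), littles_law_residents(15.1, 387)
(268, 195)
>>> str(staffing_delta(268, 195))
'3–4'
```

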