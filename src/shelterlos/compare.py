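"""Period-to-period comparison utilities.

Klein fixed-time-point tests between two stay curves, extraction of the
contiguous significant region, scans over consecutive (or year-over-year)
calendar periods with the Cox score test, an exact binomial meta-test on
the number of significant scan results, and the Little's-law translation
of mean stay into an expected resident count and staffing needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cox import score_test
from .exceptions import ValidationError
from .periods import build_exitlos, stack

__all__ = [
    "klein_pointwise",
    "significant_region",
    "consecutive_period_scan",
    "binomial_sequence_test",
    "littles_law_residents",
    "staffing_delta",
    "RegionResult",
    "StaffingDelta",
]


def klein_pointwise(fit_a, fit_b, transform="cloglog", times=None, alpha=0.05):
    """Fixed-time-point comparison of two stay curves.

    At each time t the transformed curve difference is standardised by its
    delta-method variance: ``z(t) = (g(S_A) - g(S_B)) / sqrt(v_A + v_B)``.
    The default complementary-log-log transform ``g = log(-log S)`` is the
    recommended choice; ``linear`` gives the naive curve difference with
    Greenwood variances.  Times where a transform is undefined (S equal to
    0 or 1 under cloglog) are absent from the series.

    Not a substitute for an overall test -- it extends the confidence bands
    to localise where two curves separate.
    """
    if times is None:
        times = np.union1d(fit_a.event_times_, fit_b.event_times_)
    times = np.asarray(times, dtype=float)
    s_a, s_b = fit_a.survival_at(times), fit_b.survival_at(times)
    if transform == "cloglog":
        with np.errstate(divide="ignore", invalid="ignore"):
            g_a, g_b = np.log(-np.log(s_a)), np.log(-np.log(s_b))
        v_a = fit_a.cloglog_variance_at(times)
        v_b = fit_b.cloglog_variance_at(times)
    elif transform == "linear":
        g_a, g_b = s_a, s_b
        v_a, v_b = fit_a.variance_at(times), fit_b.variance_at(times)
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (g_a - g_b) / np.sqrt(v_a + v_b)
    series = pd.DataFrame(
        {"time": times, "z": z, "p": 2 * stats.norm.sf(np.abs(z))}
    ).dropna()
    series["significant"] = series["p"] < alpha
    series.attrs["transform"] = transform
    series.attrs["alpha"] = alpha
    return series.reset_index(drop=True)


@dataclass(frozen=True)
class RegionResult:
    """Longest contiguous sub-alpha run plus isolated points outside it."""

    start: float
    end: float
    runs: tuple
    isolated: tuple

    @property
    def empty(self):
        return math.isnan(self.start)


def significant_region(series, alpha=0.05):
    """Maximal contiguous run of sub-alpha points in a Klein series.

    Contiguity means adjacent entries of the series (the series is on the
    pooled event-time grid).  Ties between equal-length runs go to the
    earliest; all runs are reported, and sub-alpha points outside the
    winning run are listed as intermittent.
    """
    sig = (series["p"] < alpha).to_numpy()
    times = series["time"].to_numpy()
    runs = []
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if not runs:
        return RegionResult(math.nan, math.nan, (), tuple(times[sig]))
    lengths = [j - i for i, j in runs]
    best = runs[int(np.argmax(lengths))]  # argmax takes the earliest maximum
    inside = np.zeros(len(sig), dtype=bool)
    inside[best[0] : best[1] + 1] = True
    isolated = tuple(times[sig & ~inside])
    return RegionResult(
        start=float(times[best[0]]),
        end=float(times[best[1]]),
        runs=tuple((float(times[i]), float(times[j])) for i, j in runs),
        isolated=isolated,
    )


def consecutive_period_scan(
    records, periods, mode="adjacent", cap=550, ties="efron", alpha=0.05, lag=4
):
    """Cox score tests across a sequence of calendar periods.

    ``adjacent`` tests each period against the one before; ``year_over_year``
    tests each period against the one ``lag`` periods earlier (4 for
    quarterly periods).  Each test is labelled by the *second* (later)
    period, whose observations get group indicator 1, so positive z means
    faster outcomes in the later period.  Observations in different periods
    are treated as independent.
    """
    if len(periods) < 2:
        raise ValidationError("need at least two periods to scan")
    if mode == "adjacent":
        pairs = [(k - 1, k) for k in range(1, len(periods))]
    elif mode == "year_over_year":
        if len(periods) <= lag:
            raise ValidationError(f"year_over_year needs more than {lag} periods")
        pairs = [(k - lag, k) for k in range(lag, len(periods))]
    else:
        raise ValidationError(f"unknown scan mode {mode!r}")

    obs_cache = {}

    def get_obs(k):
        if k not in obs_cache:
            obs_cache[k] = build_exitlos(records, periods[k], cap=cap)
        return obs_cache[k]

    rows = []
    for a, b in pairs:
        obs_a = get_obs(a).assign(group=0)
        obs_b = get_obs(b).assign(group=1)
        res = score_test(stack([obs_a, obs_b]), ties=ties)
        rows.append(
            {
                "label": periods[b].label,
                "earlier": periods[a].label,
                "later": periods[b].label,
                "z": res.z,
                "p": res.p,
                "significant": res.p < alpha,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["mode"] = mode
    out.attrs["alpha"] = alpha
    return out


def binomial_sequence_test(n_tests, n_significant, p0=0.05):
    """Exact one-sided binomial meta-test on a batch of scan results.

    P(X >= n_significant) for X ~ Binomial(n_tests, p0): the probability of
    seeing at least this many nominally significant comparisons if every
    test had null success probability p0.  Used in lieu of a
    false-discovery-rate correction of the individual P values.
    """
    if not 0 <= n_significant <= n_tests:
        raise ValidationError("need 0 <= n_significant <= n_tests")
    return float(stats.binom.sf(n_significant - 1, n_tests, p0))


def littles_law_residents(mean_los_days, monthly_intakes, days_per_month=30):
    """Expected steady-state resident count from Little's law.

    occupancy = arrival rate x mean sojourn time, i.e.
    ``monthly_intakes / days_per_month * mean_los_days`` rounded to the
    nearest integer.  Linear in each argument before rounding.
    """
    if mean_los_days <= 0 or monthly_intakes <= 0 or days_per_month <= 0:
        raise ValidationError("all Little's-law inputs must be positive")
    return int(math.floor(monthly_intakes / days_per_month * mean_los_days + 0.5))


@dataclass(frozen=True)
class StaffingDelta:
    delta: int
    attendants_low: int
    attendants_high: int

    def __str__(self):
        if self.attendants_low == self.attendants_high:
            return str(self.attendants_low)
        return f"{self.attendants_low}–{self.attendants_high}"


def staffing_delta(residents_a, residents_b, animals_per_attendant=(18, 20)):
    """Extra daily attendants implied by a resident-count change.

    With an attendant caring for 18-20 animals, a change of ``delta``
    residents needs between delta/20 and delta/18 attendants per day; each
    endpoint is rounded down to whole attendants (73 -> 3-4).
    """
    lo_cap, hi_cap = sorted(animals_per_attendant)
    delta = abs(int(residents_a) - int(residents_b))
    return StaffingDelta(
        delta=delta,
        attendants_low=delta // hi_cap,
        attendants_high=delta // lo_cap,
    )
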