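"""Product-limit (Kaplan-Meier) estimation of the stay curve, with delayed entry.

The *stay curve* S(t) is the fraction of animals still in care after an
elapsed stay of t days.  Stays are integer days with S(0) = 1; an
observation with entry time t0 and exit time T is at risk at integer day t
when t0 < t <= T.  Left truncation (t0 > 0) arises when a resident animal
enters a calendar period part-way through its stay; right censoring when
it is still resident at the period end.

Implemented from scratch on numpy: product-limit curve, Greenwood
variance, linear and complementary-log-log (exponential Greenwood)
confidence bands, restricted means with Greenwood-based standard errors,
and stay percentiles with band-inversion confidence intervals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import ValidationError

__all__ = ["KaplanMeier", "fit_km"]


def _as_arrays(durations, events, entry):
    durations = np.asarray(durations, dtype=float)
    if durations.ndim != 1 or durations.size == 0:
        raise ValidationError("durations must be a non-empty 1-d array")
    events = (
        np.ones(durations.shape, dtype=bool)
        if events is None
        else np.asarray(events, dtype=bool)
    )
    entry = (
        np.zeros(durations.shape)
        if entry is None
        else np.asarray(entry, dtype=float)
    )
    if events.shape != durations.shape or entry.shape != durations.shape:
        raise ValidationError("durations, events and entry must have equal length")
    if np.any(durations <= 0):
        raise ValidationError("exit times must be positive")
    if np.any(entry >= durations):
        raise ValidationError("every entry time must be strictly below its exit time")
    return durations, events, entry


def n_at_risk(entry, durations, times):
    """Number at risk (entry < t <= exit) at each of ``times``."""
    entry_sorted = np.sort(np.asarray(entry, dtype=float))
    exit_sorted = np.sort(np.asarray(durations, dtype=float))
    times = np.asarray(times, dtype=float)
    return np.searchsorted(entry_sorted, times, side="left") - np.searchsorted(
        exit_sorted, times, side="left"
    )


class KaplanMeier(BaseEstimator):
    """Product-limit stay-curve estimator with delayed entry.

    Parameters
    ----------
    band_method : {"cloglog", "linear"}
        Confidence-band construction.  The default complementary-log-log
        (exponential Greenwood) band is transformation-respecting and
        stays inside [0, 1]; the linear (plain Greenwood) band is exposed
        mainly for teaching and cross-checks.
    level : float
        Confidence level for bands and derived intervals.
    cap : int or None
        Analysis horizon tau in days; the default for restricted means and
        the search bound for percentiles.  The estimator does not re-censor
        the data -- apply :func:`shelterlos.periods.apply_cap` upstream.

    Attributes
    ----------
    event_times_ : ndarray of distinct event (outcome) times, ascending
    at_risk_ : ndarray, risk-set size n_j at each event time
    events_ : ndarray, number of outcomes d_j at each event time
    survival_ : ndarray, S at each event time (right-continuous step curve)
    variance_ : ndarray, Greenwood variance of S at each event time
    """

    def __init__(self, band_method="cloglog", level=0.95, cap=550):
        self.band_method = band_method
        self.level = level
        self.cap = cap

    # -- fitting -----------------------------------------------------------

    def fit(self, durations, events=None, entry=None):
        durations, events, entry = _as_arrays(durations, events, entry)
        self.n_ = durations.size
        self.max_observed_ = float(durations.max())

        event_times, d = np.unique(durations[events], return_counts=True)
        d = d.astype(float)
        n = n_at_risk(entry, durations, event_times).astype(float)
        # d_j >= 1 implies that subject is in the risk set, so n_j >= d_j >= 1.
        self.event_times_ = event_times
        self.at_risk_ = n
        self.events_ = d
        self.survival_ = np.cumprod(1.0 - d / n) if event_times.size else np.array([])

        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(n > d, d / (n * (n - d)), np.inf)
            cumsum = np.cumsum(terms)
            self.cumvar_ = cumsum  # sum d / (n (n - d)) -- shared by all variances
            var = self.survival_**2 * cumsum
        var[self.survival_ == 0] = 0.0
        self.variance_ = var

        self._entry = entry
        self._durations = durations
        self._events = events
        self._check_gaps()
        return self

    def _check_gaps(self):
        """Warn about empty risk sets strictly between first and last event."""
        if self.event_times_.size < 2:
            self.has_gaps_ = False
            return
        grid = np.arange(self.event_times_[0], self.event_times_[-1] + 1)
        self.has_gaps_ = bool(np.any(n_at_risk(self._entry, self._durations, grid) == 0))
        if self.has_gaps_:
            warnings.warn(
                "empty risk set between first and last event time; the stay "
                "curve is unidentified across the gap (product skips it)"
            )

    # -- step-function evaluation ------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "survival_"):
            raise ValidationError("estimator is not fitted")

    def _step(self, values, times, fill=1.0):
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if self.event_times_.size == 0:
            return np.full(times.shape, fill)
        idx = np.searchsorted(self.event_times_, times, side="right") - 1
        out = np.where(idx >= 0, np.take(values, np.maximum(idx, 0)), fill)
        return out

    def survival_at(self, times):
        """S(t) evaluated as a right-continuous step function (S(0) = 1)."""
        self._check_fitted()
        return self._step(self.survival_, times, fill=1.0)

    def variance_at(self, times):
        self._check_fitted()
        return self._step(self.variance_, times, fill=0.0)

    def cloglog_variance_at(self, times):
        """Delta-method variance of log(-log S(t)); NaN where S is 0 or 1."""
        self._check_fitted()
        s = self.survival_at(times)
        cum = self._step(self.cumvar_, times, fill=0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = cum / np.log(s) ** 2
        v = np.where((s <= 0.0) | (s >= 1.0), np.nan, v)
        return v

    # -- bands, means, percentiles -----------------------------------------

    def confidence_band(self, times=None, method=None, level=None):
        """Pointwise confidence band (lower, upper) at ``times``.

        Under the cloglog transform the band is undefined (NaN) where
        S is exactly 0 or 1.
        """
        self._check_fitted()
        method = method or self.band_method
        level = level or self.level
        if times is None:
            times = self.event_times_
        z = stats.norm.ppf(0.5 + level / 2)
        s = self.survival_at(times)
        if method == "cloglog":
            sigma = np.sqrt(self.cloglog_variance_at(times))
            with np.errstate(invalid="ignore", over="ignore"):
                lower = s ** np.exp(z * sigma)
                upper = s ** np.exp(-z * sigma)
            lower[np.isnan(sigma)] = np.nan
            upper[np.isnan(sigma)] = np.nan
        elif method == "linear":
            half = z * np.sqrt(self.variance_at(times))
            lower = np.clip(s - half, 0.0, 1.0)
            upper = np.clip(s + half, 0.0, 1.0)
        else:
            raise ValidationError(f"unknown band method {method!r}")
        return lower, upper

    def restricted_mean(self, tau=None):
        """Restricted mean stay: area under S on [0, tau], with its SE.

        On the integer-day grid the area is ``sum_{t=0}^{tau-1} S(t)``.
        With neither truncation nor censoring this equals the arithmetic
        mean of the tau-capped stays exactly.  The standard error follows
        the Greenwood decomposition ``SE^2 = sum_j A_j^2 d_j / (n_j (n_j -
        d_j))`` with A_j the area under S from t_j to tau.  Beyond the
        last observed time the curve is extended flat; a warning reports
        when more than 5% of the mass is extrapolated.
        """
        self._check_fitted()
        tau = self.cap if tau is None else tau
        if tau is None or tau < 1:
            raise ValidationError("tau must be a positive number of days")
        tau = int(tau)
        grid = np.arange(tau)
        s_grid = self.survival_at(grid)
        mean = float(s_grid.sum())

        s_last = float(self.survival_at([self.max_observed_])[0])
        if self.max_observed_ < tau and s_last > 0.05:
            warnings.warn(
                f"stay curve extends flat from t={self.max_observed_:.0f} to "
                f"tau={tau} with {s_last:.1%} of the mass extrapolated"
            )

        # reverse-cumulative areas: area_after[t] = sum_{u=t}^{tau-1} S(u)
        area_after = np.concatenate([np.cumsum(s_grid[::-1])[::-1], [0.0]])
        se2 = 0.0
        for t_j, n_j, d_j in zip(self.event_times_, self.at_risk_, self.events_):
            if t_j >= tau or n_j <= d_j:
                continue
            a_j = area_after[int(t_j)]
            se2 += a_j**2 * d_j / (n_j * (n_j - d_j))
        return mean, float(np.sqrt(se2))

    def percentile(self, p=0.9, with_ci=True, method=None, level=None):
        """p-th stay percentile: min{t : S(t) <= 1 - p}, on the day grid.

        The confidence interval inverts the pointwise confidence band: a
        curve as low as the lower band crosses 1 - p earliest (the lower
        time limit), one as high as the upper band crosses latest (the
        upper time limit).  Returns ``(time, ci_low, ci_high)``; entries
        are NaN when the curve (or a band) never reaches 1 - p before the
        cap.
        """
        self._check_fitted()
        if not 0 < p < 1:
            raise ValidationError("p must be in (0, 1)")
        target = 1.0 - p

        def _first_crossing(values):
            ok = ~np.isnan(values) & (values <= target + 1e-12)
            idx = np.argmax(ok) if ok.any() else -1
            return float(self.event_times_[idx]) if idx >= 0 else np.nan

        time = _first_crossing(self.survival_)
        if not with_ci:
            return time, np.nan, np.nan
        lower_band, upper_band = self.confidence_band(
            self.event_times_, method=method, level=level
        )
        return time, _first_crossing(lower_band), _first_crossing(upper_band)

    def median(self, **kwargs):
        """Median stay (de-emphasized: it sits in the rapid initial drop)."""
        return self.percentile(0.5, **kwargs)

    def to_frame(self, method=None, level=None):
        """Export t, n_risk, n_event, S, se, lower, upper as a DataFrame."""
        self._check_fitted()
        lower, upper = self.confidence_band(method=method, level=level)
        return pd.DataFrame(
            {
                "t": self.event_times_.astype(int),
                "n_risk": self.at_risk_.astype(int),
                "n_event": self.events_.astype(int),
                "survival": self.survival_,
                "se": np.sqrt(self.variance_),
                "lower": lower,
                "upper": upper,
            }
        )


def fit_km(observations, cap=550, **params):
    """Fit a :class:`KaplanMeier` from an observation DataFrame.

    ``observations`` needs columns ``entry_time``, ``exit_time``, ``event``
    (as produced by :mod:`shelterlos.periods`).
    """
    km = KaplanMeier(cap=cap, **params)
    return km.fit(
        observations["exit_time"].to_numpy(dtype=float),
        observations["event"].to_numpy(dtype=bool),
        observations["entry_time"].to_numpy(dtype=float),
    )
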