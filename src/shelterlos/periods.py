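"""Calendar-period observation construction.

Two ways to attach stays to a calendar period:

* **HistLOS** -- the computation historically used by shelters: take the
  full intake-to-outcome stay of every animal whose *outcome* fell in the
  period.  Animals still in care contribute nothing, which biases period
  comparisons whenever long-stay residents accumulate or depart.

* **ExitLOS** -- every animal in care for any fraction of the period
  contributes one observation.  A stay is left-truncated at the period
  start (the animal enters the risk set at its already-elapsed stay
  ``entry_time``) and right-censored at the period end (``event=False``
  with ``exit_time`` equal to the elapsed stay at the boundary).  Elapsed
  time always counts from intake; it does not reset at the period start.

Observations are plain pandas DataFrames with columns ``animal_id,
period_label, entry_time, exit_time, event, truncated, censored, size,
age``.  Risk-set membership at integer day ``t`` is
``entry_time < t <= exit_time``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, IdentityError, ValidationError
from .records import full_los

DEFAULT_CAP = 550

OBSERVATION_COLUMNS = (
    "animal_id", "period_label", "entry_time", "exit_time",
    "event", "truncated", "censored", "size", "age",
)


@dataclass(frozen=True)
class PeriodWindow:
    """A calendar period with inclusive endpoints, labelled 'YY-MM' by default."""

    start: pd.Timestamp
    end: pd.Timestamp
    label: str = field(default=None)

    def __post_init__(self):
        start = pd.Timestamp(self.start)
        end = pd.Timestamp(self.end)
        if start > end:
            raise ValidationError(f"period start {start.date()} after end {end.date()}")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if self.label is None:
            object.__setattr__(self, "label", f"{start:%y-%m}")

    @property
    def n_days(self):
        return (self.end - self.start).days + 1


def make_periods(start, end, granularity="quarterly"):
    """Contiguous, non-overlapping periods covering ``[start, end]``.

    ``granularity`` is ``"monthly"``, ``"quarterly"``, or an explicit list
    of ``(start, end)`` pairs / :class:`PeriodWindow` objects.  Monthly and
    quarterly periods must align to whole months (and, for quarterly, the
    range must span a whole number of quarters).
    """
    if isinstance(granularity, (list, tuple)):
        periods = [
            p if isinstance(p, PeriodWindow) else PeriodWindow(*p) for p in granularity
        ]
        for a, b in zip(periods, periods[1:]):
            if b.start != a.end + pd.Timedelta(days=1):
                raise AlignmentError(
                    f"custom periods {a.label} and {b.label} are not contiguous"
                )
        return periods

    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start.day != 1:
        raise AlignmentError(f"start {start.date()} is not the first of a month")
    if (end + pd.Timedelta(days=1)).day != 1:
        raise AlignmentError(f"end {end.date()} is not the last day of a month")
    n_months = (end.year - start.year) * 12 + end.month - start.month + 1
    if granularity == "monthly":
        step = 1
    elif granularity == "quarterly":
        step = 3
        if n_months % 3:
            raise AlignmentError(f"{n_months} months do not form whole quarters")
    else:
        raise ValidationError(f"unknown granularity {granularity!r}")
    periods = []
    for k in range(0, n_months, step):
        p_start = start + pd.DateOffset(months=k)
        p_end = start + pd.DateOffset(months=k + step) - pd.Timedelta(days=1)
        periods.append(PeriodWindow(p_start, p_end))
    return periods


def apply_cap(observations, cap=DEFAULT_CAP):
    """Administratively censor stays at ``cap`` days.

    Exit times beyond the cap are pulled back to the cap and the event flag
    is cleared (the eventual outcome is beyond the analysis horizon).
    Observations whose entire in-period window lies beyond the cap
    (``entry_time >= cap``) carry no usable information and are dropped
    with a warning.
    """
    if cap is None:
        return observations
    if cap < 1:
        raise ValidationError(f"cap must be >= 1, got {cap}")
    obs = observations.copy()
    dropped = obs["entry_time"] >= cap
    if dropped.any():
        warnings.warn(f"dropping {int(dropped.sum())} observations with entry_time >= cap ({cap})")
        obs = obs[~dropped].copy()
    over = obs["exit_time"] > cap
    obs.loc[over, "exit_time"] = cap
    obs.loc[over, "event"] = False
    obs.loc[over, "censored"] = True
    return obs.reset_index(drop=True)


def _covariates(records):
    cov = {}
    if "size" in records.columns:
        cov["size"] = records["size"].to_numpy()
    else:
        cov["size"] = np.full(len(records), "UNKNOWN", dtype=object)
    if "age" in records.columns:
        cov["age"] = records["age"].to_numpy(dtype=object)
    else:
        cov["age"] = np.full(len(records), pd.NA, dtype=object)
    return cov


def build_exitlos(records, period, cap=DEFAULT_CAP, extract_date=None):
    """ExitLOS observations for one period (left-truncated, right-censored).

    Includes every record whose stay overlaps the period for at least one
    calendar day: ``intake <= period.end`` and (no outcome yet, or
    ``outcome >= period.start``).  A record with no outcome is assumed
    still resident through the data-extract date; pass ``extract_date`` to
    refuse periods that extend beyond the extract.
    """
    if extract_date is not None and period.end > pd.Timestamp(extract_date):
        raise ValidationError(
            f"period {period.label} ends {period.end.date()}, after the data "
            f"extract date {pd.Timestamp(extract_date).date()}"
        )
    bad = records["outcome_date"].notna() & (records["outcome_date"] < records["intake_date"])
    if bad.any():
        raise ValidationError(f"{int(bad.sum())} records have outcome before intake")

    intake = records["intake_date"]
    outcome = records["outcome_date"]
    in_period = (intake <= period.end) & (outcome.isna() | (outcome >= period.start))
    sub = records[in_period]

    entry = np.maximum((period.start - sub["intake_date"]).dt.days.to_numpy(), 0)
    event = (sub["outcome_date"].notna() & (sub["outcome_date"] <= period.end)).to_numpy()
    exit_days = np.where(
        event,
        full_los(sub, allow_missing=True).to_numpy(dtype=float, na_value=np.nan),
        (period.end - sub["intake_date"]).dt.days.to_numpy() + 1,
    ).astype(int)

    cov = _covariates(sub)
    obs = pd.DataFrame(
        {
            "animal_id": sub["animal_id"].to_numpy(),
            "period_label": period.label,
            "entry_time": entry,
            "exit_time": exit_days,
            "event": event,
            "truncated": entry > 0,
            "censored": ~event,
            "size": cov["size"],
            "age": pd.array(cov["age"], dtype="Int64"),
        }
    )
    return apply_cap(obs, cap)


def build_histlos(records, period, cap=DEFAULT_CAP):
    """HistLOS observations: full stays of animals with in-period outcomes."""
    outcome = records["outcome_date"]
    mask = outcome.notna() & (outcome >= period.start) & (outcome <= period.end)
    sub = records[mask]
    cov = _covariates(sub)
    obs = pd.DataFrame(
        {
            "animal_id": sub["animal_id"].to_numpy(),
            "period_label": period.label,
            "entry_time": 0,
            "exit_time": full_los(sub).to_numpy(dtype=int),
            "event": True,
            "truncated": False,
            "censored": False,
            "size": cov["size"],
            "age": pd.array(cov["age"], dtype="Int64"),
        }
    )
    return apply_cap(obs, cap)


def stack(collections):
    """Concatenate observation collections, keeping per-observation labels."""
    frames = [c for c in collections]
    if not frames:
        return pd.DataFrame(columns=list(OBSERVATION_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def boundary_identities(records, periods, cap=None, strict=True):
    """Check the period-boundary bookkeeping identities on contiguous periods.

    For each period: non-truncated observations = in-period intakes and
    non-censored observations = in-period outcomes.  For each adjacent
    pair: censored observations of period k = truncated observations of
    period k+1 (both count the residents at the shared boundary).

    Identities are checked on uncapped observations by default, because
    administrative censoring at the cap can drop a later-period truncated
    observation whose earlier-period censored counterpart is retained.

    Returns a report DataFrame; with ``strict`` an :class:`IdentityError`
    naming the failing period is raised if any identity fails.
    """
    for a, b in zip(periods, periods[1:]):
        if b.start != a.end + pd.Timedelta(days=1):
            raise ValidationError(f"periods {a.label}, {b.label} are not contiguous")

    obs = [build_exitlos(records, p, cap=cap) for p in periods]
    rows = []
    for k, (p, o) in enumerate(zip(periods, obs)):
        intakes = int(
            ((records["intake_date"] >= p.start) & (records["intake_date"] <= p.end)).sum()
        )
        outcomes = int(
            (
                records["outcome_date"].notna()
                & (records["outcome_date"] >= p.start)
                & (records["outcome_date"] <= p.end)
            ).sum()
        )
        row = {
            "period": p.label,
            "n_obs": len(o),
            "intakes": intakes,
            "outcomes": outcomes,
            "not_truncated": int((~o["truncated"]).sum()),
            "not_censored": int((~o["censored"]).sum()),
            "truncated": int(o["truncated"].sum()),
            "censored": int(o["censored"].sum()),
        }
        row["intakes_ok"] = row["not_truncated"] == intakes
        row["outcomes_ok"] = row["not_censored"] == outcomes
        if k + 1 < len(periods):
            row["boundary_ok"] = row["censored"] == int(obs[k + 1]["truncated"].sum())
        else:
            row["boundary_ok"] = True
        rows.append(row)
    report = pd.DataFrame(rows)
    if strict:
        bad = report[~(report["intakes_ok"] & report["outcomes_ok"] & report["boundary_ok"])]
        if len(bad):
            raise IdentityError(
                "boundary identities failed for periods: "
                + ", ".join(bad["period"].tolist())
            )
    return report


_CELLS = (
    ("All", None),
    ("Not Truncated", lambda o: ~o["truncated"]),
    ("Left-Truncated", lambda o: o["truncated"]),
    ("Not Censored", lambda o: ~o["censored"]),
    ("Right-Censored", lambda o: o["censored"]),
    ("Not Truncated & Not Censored", lambda o: ~o["truncated"] & ~o["censored"]),
    ("Not Truncated & Right-Censored", lambda o: ~o["truncated"] & o["censored"]),
    ("Left-Truncated & Not Censored", lambda o: o["truncated"] & ~o["censored"]),
    ("Left-Truncated & Right-Censored", lambda o: o["truncated"] & o["censored"]),
)


def describe_observations(observations):
    """Descriptive stay statistics by truncation x censoring cell.

    The stay is ``exit_time`` -- days from intake to outcome or censoring.
    """
    rows = []
    for name, selector in _CELLS:
        sub = observations if selector is None else observations[selector(observations)]
        stays = sub["exit_time"]
        rows.append(
            {
                "cell": name,
                "count": len(sub),
                "mean": float(stays.mean()) if len(sub) else np.nan,
                "std": float(stays.std(ddof=1)) if len(sub) > 1 else np.nan,
                "min": int(stays.min()) if len(sub) else np.nan,
                "max": int(stays.max()) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cell")
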