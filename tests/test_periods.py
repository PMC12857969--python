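"""Period construction and the truncation/censoring observation slicing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shelterlos.exceptions import AlignmentError, ValidationError
from shelterlos.periods import (
    PeriodWindow,
    apply_cap,
    boundary_identities,
    build_exitlos,
    build_histlos,
    describe_observations,
    make_periods,
    stack,
)

from conftest import make_records

OCT = PeriodWindow("2023-10-01", "2023-10-31")
NOV = PeriodWindow("2023-11-01", "2023-11-30")


def test_make_periods_quarterly_and_monthly():
    quarters = make_periods("2018-07-01", "2024-06-30", "quarterly")
    assert len(quarters) == 24
    assert quarters[0].label == "18-07" and quarters[-1].label == "24-04"
    assert all(
        b.start == a.end + pd.Timedelta(days=1) for a, b in zip(quarters, quarters[1:])
    )
    months = make_periods("2023-10-01", "2023-11-30", "monthly")
    assert [m.label for m in months] == ["23-10", "23-11"]


@pytest.mark.parametrize(
    "start, end", [("2023-10-15", "2023-11-30"), ("2023-10-01", "2023-11-15")]
)
def test_make_periods_misaligned_boundaries(start, end):
    with pytest.raises(AlignmentError):
        make_periods(start, end, "monthly")


def test_make_periods_quarterly_requires_whole_quarters():
    with pytest.raises(AlignmentError):
        make_periods("2023-10-01", "2023-11-30", "quarterly")


def test_exitlos_four_overlap_cases():
    records = make_records(
        [
            # fully observed within October
            ("full", "2023-10-05", "2023-10-20", "STRAY", "ADOPTION", "MED", None),
            # the minimum possible truncated stay: in care the day before the
            # period, exits on the period's first day -> entry 1, stay 2
            ("trunc", "2023-09-30", "2023-10-01", "STRAY", "ADOPTION", "MED", None),
            # arrives on day one, still resident at month end
            ("cens", "2023-10-01", None, "STRAY", None, "MED", None),
            # resident throughout: truncated and censored
            ("both", "2023-09-20", None, "STRAY", None, "MED", None),
            # left before the period: excluded
            ("gone", "2023-09-01", "2023-09-15", "STRAY", "ADOPTION", "MED", None),
            # arrives after the period: excluded
            ("later", "2023-11-02", None, "STRAY", None, "MED", None),
        ]
    )
    obs = build_exitlos(records, OCT).set_index("animal_id")
    assert set(obs.index) == {"full", "trunc", "cens", "both"}
    assert obs.loc["full", ["entry_time", "exit_time", "event"]].tolist() == [0, 16, True]
    assert obs.loc["trunc", ["entry_time", "exit_time", "event"]].tolist() == [1, 2, True]
    assert obs.loc["cens", ["entry_time", "exit_time", "event"]].tolist() == [0, 31, False]
    assert obs.loc["both", ["entry_time", "exit_time", "event"]].tolist() == [11, 42, False]
    assert obs.loc["both", "truncated"] and obs.loc["both", "censored"]
    assert (obs["entry_time"] < obs["exit_time"]).all()


def test_histlos_only_in_period_outcomes():
    records = make_records(
        [
            ("old", "2023-04-10", "2023-10-10", "STRAY", "ADOPTION", "MED", None),
            ("after", "2023-10-20", "2023-11-01", "STRAY", "ADOPTION", "MED", None),
            ("resident", "2023-10-05", None, "STRAY", None, "MED", None),
        ]
    )
    obs = build_histlos(records, OCT)
    # only the stay that *ended* in October counts, with its full length
    assert list(obs["animal_id"]) == ["old"]
    assert obs.loc[0, ["entry_time", "exit_time", "event", "truncated"]].tolist() == [
        0, 184, True, False,
    ]


def test_apply_cap_administrative_censoring():
    obs = pd.DataFrame(
        {
            "animal_id": ["a", "b", "c", "d"],
            "period_label": "p",
            "entry_time": [0, 0, 0, 560],
            "exit_time": [600, 550, 10, 580],
            "event": [True, True, True, True],
            "truncated": [False, False, False, True],
            "censored": [False, False, False, False],
        }
    )
    with pytest.warns(UserWarning, match="entry_time >= cap"):
        capped = apply_cap(obs, 550)
    capped = capped.set_index("animal_id")
    assert "d" not in capped.index  # window entirely beyond the horizon
    assert capped.loc["a", ["exit_time", "event"]].tolist() == [550, False]
    assert capped.loc["b", ["exit_time", "event"]].tolist() == [550, True]  # boundary
    assert capped.loc["c", ["exit_time", "event"]].tolist() == [10, True]


def test_extract_date_refuses_open_period():
    records = make_records([("a", "2023-10-05", None, "STRAY", None, "MED", None)])
    with pytest.raises(ValidationError, match="extract"):
        build_exitlos(records, OCT, extract_date="2023-10-15")
    assert len(build_exitlos(records, OCT, extract_date="2023-10-31")) == 1


def test_single_record_spanning_three_periods():
    records = make_records(
        [("a", "2023-09-20", "2023-11-10", "STRAY", "ADOPTION", "MED", None)]
    )
    periods = make_periods("2023-09-01", "2023-11-30", "monthly")
    obs = stack([build_exitlos(records, p) for p in periods])
    assert len(obs) == 3
    middle = obs[obs["period_label"] == "23-10"].iloc[0]
    assert middle["truncated"] and middle["censored"]
    report = boundary_identities(records, periods)
    assert report[["intakes_ok", "outcomes_ok", "boundary_ok"]].all().all()


def test_boundary_identities_empty_records():
    records = make_records([])
    report = boundary_identities(records, [OCT, NOV])
    assert (report[["n_obs", "intakes", "outcomes"]] == 0).all().all()


def test_stack_preserves_counts_and_labels(sim_records):
    obs_oct = build_exitlos(sim_records, OCT)
    obs_nov = build_exitlos(sim_records, NOV)
    stacked = stack([obs_oct, obs_nov])
    assert len(stacked) == len(obs_oct) + len(obs_nov)
    assert stack([obs_oct]).equals(obs_oct)
    assert stack([]).empty
    # unified-minus-stacked difference = residents crossing the boundary
    unified = build_exitlos(
        sim_records, PeriodWindow(OCT.start, NOV.end, label="unified")
    )
    crossers = int(obs_oct["censored"].sum())
    assert len(stacked) - len(unified) == crossers
    assert crossers == int(obs_nov["truncated"].sum())


def test_describe_observations_table_shape(sim_records):
    desc = describe_observations(build_exitlos(sim_records, OCT))
    assert desc.loc["All", "count"] == (
        desc.loc["Not Truncated", "count"] + desc.loc["Left-Truncated", "count"]
    )
    four_cells = [
        "Not Truncated & Not Censored", "Not Truncated & Right-Censored",
        "Left-Truncated & Not Censored", "Left-Truncated & Right-Censored",
    ]
    assert desc.loc[four_cells, "count"].sum() == desc.loc["All", "count"]
    trunc = desc.loc["Left-Truncated"]
    if trunc["count"]:
        assert trunc["min"] >= 2  # a truncated stay spans at least two days


@given(st.data())
@settings(max_examples=30, derandomize=True, deadline=None)
def test_random_slicings_satisfy_identities(data):
    n = data.draw(st.integers(1, 25))
    rows = []
    for i in range(n):
        intake = data.draw(st.integers(0, 80))
        stay = data.draw(st.one_of(st.none(), st.integers(0, 120)))
        rows.append(
            (
                f"a{i}",
                pd.Timestamp("2023-01-01") + pd.Timedelta(days=intake),
                None if stay is None else pd.Timestamp("2023-01-01") + pd.Timedelta(days=intake + stay),
                "STRAY", "ADOPTION", "MED", None,
            )
        )
    records = make_records(rows)
    periods = make_periods("2023-01-01", "2023-06-30", "monthly")
    boundary_identities(records, periods, strict=True)
    for p in periods:
        exitlos = build_exitlos(records, p, cap=None)
        histlos = build_histlos(records, p, cap=None)
        assert len(exitlos) >= len(histlos)
        assert (exitlos["entry_time"] < exitlos["exit_time"]).all()
        assert (exitlos["truncated"] == (exitlos["entry_time"] > 0)).all()
        assert (exitlos["censored"] == ~exitlos["event"]).all()
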