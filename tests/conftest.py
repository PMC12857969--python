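"""Shared fixtures: hand-built record tables and fast discrete-PH samplers."""

import numpy as np
import pandas as pd
import pytest

from shelterlos.simulate import SimulationConfig, simulate_records


def make_records(rows):
    """Build a canonical record table from (id, intake, outcome, itype, otype, size, dob)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "animal_id", "intake_date", "outcome_date",
            "intake_type", "outcome_type", "size", "date_of_birth",
        ],
    )
    for col in ("intake_date", "outcome_date", "date_of_birth"):
        df[col] = pd.to_datetime(df[col])
    return df


@pytest.fixture(scope="session")
def sim_records():
    """One year of synthetic records at municipal-shelter scale."""
    return simulate_records(SimulationConfig(seed=42))


def draw_discrete_ph_stays(rng, n, eta, baseline, horizon=550):
    """Sample integer-day stays from a discrete proportional-hazards model.

    Under the complementary-log-log link the per-subject stay curve is
    S0(t) ** exp(eta), so stays can be drawn by inverting the baseline
    curve: stay = min{t : S0(t) < U ** (1 / exp(eta))}.  Stays beyond
    ``horizon`` are censored there.
    """
    s0 = baseline.survival(np.arange(horizon + 1))
    u = rng.random(n) ** (1.0 / np.exp(np.asarray(eta, dtype=float)))
    # searchsorted on the descending S0 grid
    stays = np.searchsorted(-s0, -u, side="right")
    stays = np.clip(stays, 1, None)
    event = stays <= horizon
    stays = np.minimum(stays, horizon)
    return stays.astype(float), event
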