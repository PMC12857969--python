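"""Cox model: likelihood mechanics, diagnostics, and simulation recovery."""

import numpy as np
import pandas as pd
import pytest

from shelterlos.cox import (
    CoxPH,
    fit_cox,
    fit_cox_stratified,
    log_cumulative_hazard_curves,
    nelson_aalen,
    score_test,
)
from shelterlos.exceptions import SeparationError, StatisticalError, ValidationError
from shelterlos.simulate import GeometricMixtureHazard

from conftest import draw_discrete_ph_stays


def _two_group_frame(rng, n=400, log_hr=0.0, baseline=None, entry_frac=0.0):
    baseline = baseline or GeometricMixtureHazard()
    group = rng.integers(0, 2, n)
    stays, event = draw_discrete_ph_stays(rng, n, group * log_hr, baseline)
    entry = np.zeros(n)
    if entry_frac:
        delayed = rng.random(n) < entry_frac
        entry[delayed] = np.minimum(rng.integers(1, 10, n), stays.astype(int) - 1)[delayed]
        entry = np.clip(entry, 0, None)
    keep = entry < stays
    return pd.DataFrame(
        {
            "entry_time": entry[keep],
            "exit_time": stays[keep],
            "event": event[keep],
            "group": group[keep],
        }
    )


def test_no_ties_efron_equals_breslow():
    rng = np.random.default_rng(0)
    n = 60
    dur = rng.permutation(np.arange(1.0, n + 1))
    ev = rng.random(n) < 0.7
    x = rng.normal(size=n)
    a = CoxPH(ties="efron").fit(x, dur, ev)
    b = CoxPH(ties="breslow").fit(x, dur, ev)
    assert np.isclose(a.log_likelihood_, b.log_likelihood_, atol=1e-10)
    assert np.allclose(a.coef_, b.coef_, atol=1e-8)


def test_constant_covariate_is_rejected():
    with pytest.raises(ValidationError, match="constant"):
        CoxPH().fit(np.ones(10), np.arange(1.0, 11.0), np.ones(10, bool))


def test_separation_is_detected():
    # covariate = -exit time with all events: likelihood is monotone in beta
    dur = np.arange(1.0, 31.0)
    with pytest.raises(SeparationError):
        CoxPH().fit(-dur, dur, np.ones(30, bool))


def test_simulated_hazard_ratio_recovery():
    rng = np.random.default_rng(5)
    obs = _two_group_frame(rng, n=5000, log_hr=np.log(0.8))
    fit = fit_cox(obs, "group")
    assert abs(fit.coef_[0] - np.log(0.8)) < 3 * fit.se_[0]
    # orientation: group 1 with HR < 1 exits slower, so the score z is negative
    assert score_test(obs).z < 0


def test_score_test_sign_and_relabeling():
    rng = np.random.default_rng(6)
    obs = _two_group_frame(rng, n=1500, log_hr=np.log(1.5))
    res = score_test(obs)
    assert res.z > 0  # faster outcomes in the later group
    flipped = obs.assign(group=1 - obs["group"])
    res2 = score_test(flipped)
    assert np.isclose(res.p, res2.p, atol=1e-12)
    assert np.isclose(res.z, -res2.z, atol=1e-12)


def test_stratified_single_stratum_matches_plain():
    rng = np.random.default_rng(7)
    obs = _two_group_frame(rng, n=300, log_hr=np.log(0.7))
    plain = fit_cox(obs, "group")
    single = CoxPH().fit(
        obs[["group"]].to_numpy(float),
        obs["exit_time"].to_numpy(),
        obs["event"].to_numpy(),
        obs["entry_time"].to_numpy(),
        strata=np.zeros(len(obs), dtype=object),
    )
    assert np.allclose(plain.coef_, single.coef_, atol=1e-10)
    assert np.allclose(plain.se_, single.se_, atol=1e-10)


def test_stratified_recovers_common_effect_across_baselines():
    rng = np.random.default_rng(8)
    frames = []
    for label, probs in (("fast", (0.3, 0.05)), ("slow", (0.1, 0.02))):
        f = _two_group_frame(
            rng, n=2500, log_hr=np.log(0.8), baseline=GeometricMixtureHazard(probs=probs)
        )
        f["cell"] = label
        frames.append(f)
    obs = pd.concat(frames, ignore_index=True)
    fit = CoxPH().fit(
        obs[["group"]].to_numpy(float),
        obs["exit_time"].to_numpy(),
        obs["event"].to_numpy(),
        obs["entry_time"].to_numpy(),
        strata=obs["cell"].to_numpy(object),
    )
    assert abs(fit.coef_[0] - np.log(0.8)) < 3 * fit.se_[0]
    assert set(fit.baseline_cumulative_hazard_) == {"fast", "slow"}


def test_stratum_without_events_is_excluded_with_warning():
    rng = np.random.default_rng(9)
    obs = _two_group_frame(rng, n=200, log_hr=0.0)
    extra = pd.DataFrame(
        {"entry_time": [0.0, 0.0], "exit_time": [5.0, 7.0], "event": [False, False],
         "group": [0, 1]}
    )
    strata = np.array(["a"] * len(obs) + ["empty"] * 2, dtype=object)
    both = pd.concat([obs, extra], ignore_index=True)
    with pytest.warns(UserWarning, match="no events"):
        fit = CoxPH().fit(
            both[["group"]].to_numpy(float),
            both["exit_time"].to_numpy(),
            both["event"].to_numpy(),
            strata=strata,
        )
    assert fit.dropped_strata_ == ["empty"]


def test_breslow_baseline_reduces_to_nelson_aalen_at_null():
    rng = np.random.default_rng(10)
    obs = _two_group_frame(rng, n=300, log_hr=0.0)
    # beta forced to 0 by symmetry: identical groups duplicated
    dup = pd.concat([obs.assign(group=0), obs.assign(group=1)], ignore_index=True)
    fit = fit_cox(dup, "group")
    assert abs(fit.coef_[0]) < 1e-6
    t, h = fit.baseline_cumulative_hazard_[fit.strata_[0]]
    na_t, na_h = nelson_aalen(dup)
    assert np.allclose(t, na_t) and np.allclose(h, na_h, atol=1e-6)
    assert (np.diff(h) >= 0).all()
    # by symmetry a fully symmetric two-group toy pins beta = 0, and the
    # first baseline jump is d_1 / n
    toy = CoxPH().fit(
        np.array([0.0, 1.0, 0.0, 1.0]), [1.0, 1.0, 2.0, 2.0], np.ones(4, bool)
    )
    tt, hh = toy.baseline_cumulative_hazard_[toy.strata_[0]]
    assert abs(toy.coef_[0]) < 1e-8
    assert np.isclose(hh[0], 2 / 4)


def test_schoenfeld_residuals_sum_to_zero_at_mle():
    rng = np.random.default_rng(11)
    obs = _two_group_frame(rng, n=500, log_hr=np.log(0.8), entry_frac=0.3)
    fit = fit_cox(obs, "group")
    resid = fit.schoenfeld_residuals()
    assert abs(resid["x0"].sum()) < 1e-6
    scaled = fit.schoenfeld_residuals(scaled=True)
    assert len(scaled) == fit.n_events_


def test_zph_requires_events_and_reports_shape():
    rng = np.random.default_rng(12)
    obs = _two_group_frame(rng, n=800, log_hr=np.log(0.8))
    fit = fit_cox(obs, "group")
    table = fit.zph()
    assert list(table.columns) == ["term", "chi2", "df", "p", "transform"]
    assert table.loc[0, "df"] == 1 and 0 <= table.loc[0, "p"] <= 1
    tiny = CoxPH().fit([0.0, 1.0, 0.0], [1.0, 2.0, 3.0], [True, False, False])
    with pytest.raises(StatisticalError):
        tiny.zph()
    with pytest.raises(ValidationError):
        fit.zph(transform="nope")


def test_zph_detects_strongly_time_varying_effect():
    # effect reverses over time: group 1 fast early, slow late
    rng = np.random.default_rng(13)
    n = 1500
    group = rng.integers(0, 2, n)
    early = rng.random(n) < 0.5
    stays = np.where(
        group == 1, np.where(early, rng.integers(1, 4, n), rng.integers(40, 80, n)),
        rng.integers(1, 60, n),
    ).astype(float)
    obs = pd.DataFrame(
        {"entry_time": 0.0, "exit_time": stays, "event": True, "group": group}
    )
    fit = fit_cox(obs, "group")
    assert fit.zph().loc[0, "p"] < 0.01


def test_martingale_and_deviance_residuals():
    rng = np.random.default_rng(14)
    obs = _two_group_frame(rng, n=2000, log_hr=np.log(0.8), entry_frac=0.2)
    fit = fit_cox(obs, "group")
    m = fit.martingale_residuals()
    assert abs(m.sum()) < 1e-6  # estimating equation at the MLE
    dev, frac = fit.deviance_residuals()
    assert 0.005 < frac < 0.12  # roughly the few-percent outlier share expected
    # censored observation with no accumulated hazard has residual exactly 0
    toy = CoxPH().fit(
        np.array([1.0, 0.0, 1.0]), [2.0, 3.0, 4.0], [True, True, False], [0.0, 0.0, 3.0]
    )
    # the censored subject entered at t0=3 and was censored at 4 with no
    # event time in (3, 4]: zero hazard increment, zero residual
    assert toy.martingale_residuals()[-1] == 0.0
    assert toy.deviance_residuals()[0][-1] == 0.0


def test_log_cumulative_hazard_curves_parallelism():
    rng = np.random.default_rng(15)
    # small per-day hazards so the discrete Nelson-Aalen sum is close to the
    # continuous cumulative hazard
    slow = GeometricMixtureHazard(probs=(0.05, 0.01), weights=(0.8, 0.2))
    obs = _two_group_frame(rng, n=6000, log_hr=np.log(0.5), baseline=slow)
    groups = {g: obs[obs["group"] == g] for g in (0, 1)}
    curves = log_cumulative_hazard_curves(groups)
    # identical groups give identical curves
    same = log_cumulative_hazard_curves({"a": groups[0], "b": groups[0]})
    assert same["a"].equals(same["b"])
    # vertical offset approximates the log hazard ratio in the data-dense range
    common = np.intersect1d(curves[0]["time"], curves[1]["time"])
    common = common[(common >= 3) & (common <= 25)]
    c0 = curves[0].set_index("time").loc[common, "log_cum_hazard"]
    c1 = curves[1].set_index("time").loc[common, "log_cum_hazard"]
    offsets = (c1 - c0).to_numpy()
    assert abs(np.median(offsets) - np.log(0.5)) < 0.1
    assert offsets.std() < 0.1
    # Nelson-Aalen tracks -log(KM) on dense data
    from shelterlos.km import fit_km

    km = fit_km(groups[0], cap=None)
    t, h = nelson_aalen(groups[0])
    mid = (t >= 2) & (t <= 20)
    assert np.allclose(h[mid], -np.log(km.survival_at(t[mid])), rtol=0.05)


def test_summary_table_contents():
    rng = np.random.default_rng(16)
    obs = _two_group_frame(rng, n=800, log_hr=np.log(0.8))
    fit = fit_cox(obs, "group")
    row = fit.summary(names=["later"]).iloc[0]
    assert row["term"] == "later"
    assert np.isclose(row["hazard_ratio"], np.exp(row["coef"]))
    assert row["hr_lower"] < row["hazard_ratio"] < row["hr_upper"]
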