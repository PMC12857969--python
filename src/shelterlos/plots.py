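"""Figure routines: stay curves with bands, scan panels, period summaries.

Every figure has a machine-readable CSV twin produced by the CLI; plots
never embed numbers absent from those tables.
"""

from __future__ import annotations

import numpy as np

from .compare import klein_pointwise


def plot_km(fits, ax=None, alpha=0.05, klein=True, max_time=None):
    """Stay curves with confidence bands for one or more fitted estimators.

    ``fits`` maps a label to a fitted :class:`~shelterlos.km.KaplanMeier`.
    Censor marks sit on the curves; truncation entry-time marks are drawn
    color-coded along the top and bottom edges.  With two fits and
    ``klein``, time points where the Klein test has P < alpha are shaded.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    edges = iter((1.02, -0.02, 1.05, -0.05))
    for (label, km), edge in zip(fits.items(), edges):
        t_max = max_time or (km.cap or km.max_observed_)
        grid = np.arange(0, int(min(t_max, km.max_observed_)) + 1)
        s = km.survival_at(grid)
        (line,) = ax.step(grid, s, where="post", label=label)
        lower, upper = km.confidence_band(grid)
        ax.fill_between(grid, lower, upper, step="post", alpha=0.2, color=line.get_color())
        cens = km._durations[~km._events]
        ax.plot(cens, km.survival_at(cens), "|", color=line.get_color(), ms=6, alpha=0.5)
        entries = km._entry[km._entry > 0]
        if entries.size:
            ax.plot(entries, np.full(entries.size, edge), "|", ms=6,
                    color=line.get_color(), alpha=0.5, clip_on=False)
    if klein and len(fits) == 2:
        fit_a, fit_b = fits.values()
        series = klein_pointwise(fit_a, fit_b, alpha=alpha)
        sig = series[series["significant"]]
        if len(sig):
            ax.plot(sig["time"], np.full(len(sig), -0.08), ".", ms=3,
                    color="0.3", clip_on=False,
                    label=f"Klein P < {alpha:g}")
    ax.set_xlabel("elapsed stay (days)")
    ax.set_ylabel("fraction remaining in care")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def plot_scan(scan, ax=None, alpha=0.05):
    """Two-panel scan plot: score z on top, P value below, dashed alpha line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    ax_z, ax_p = ax
    x = np.arange(len(scan))
    ax_z.axhline(0, color="0.7", lw=0.8)
    ax_z.plot(x, scan["z"], "o-")
    ax_z.set_ylabel("Cox score z")
    ax_p.plot(x, scan["p"], "o-")
    ax_p.axhline(alpha, ls="--", color="0.3")
    ax_p.set_yscale("log")
    ax_p.set_ylabel("P value")
    ax_p.set_xticks(x, scan["label"], rotation=60)
    return ax


def plot_period_summary(summary, overall_mean=None, overall_p90=None, ax=None):
    """Per-period restricted means and 90th percentiles with CI bands.

    ``summary`` needs columns label, mean, mean_lower, mean_upper, p90,
    p90_lower, p90_upper.  Dashed lines show whole-range reference values.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    ax_m, ax_p = ax
    x = np.arange(len(summary))
    ax_m.plot(x, summary["mean"], "o-")
    ax_m.fill_between(x, summary["mean_lower"], summary["mean_upper"], alpha=0.2)
    if overall_mean is not None:
        ax_m.axhline(overall_mean, ls="--", color="0.3")
    ax_m.set_ylabel("mean stay (days)")
    ax_p.plot(x, summary["p90"], "o-")
    ax_p.fill_between(x, summary["p90_lower"], summary["p90_upper"], alpha=0.2)
    if overall_p90 is not None:
        ax_p.axhline(overall_p90, ls="--", color="0.3")
    ax_p.set_ylabel("90th stay percentile (days)")
    ax_p.set_xticks(x, summary["label"], rotation=60)
    return ax


def plot_log_cumulative_hazard(curves, ax=None):
    """Log cumulative hazard vs log time; parallel lines support PH."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for label, df in curves.items():
        ax.step(df["log_time"], df["log_cum_hazard"], where="post", label=label)
    ax.set_xlabel("log elapsed stay")
    ax.set_ylabel("log cumulative exit hazard")
    ax.legend()
    return ax


def plot_residual_panels(schoenfeld, deviance, axes=None):
    """Schoenfeld residuals over time and deviance residuals by index."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(11, 4))
    ax_s, ax_d = axes
    cols = [c for c in schoenfeld.columns if c.startswith("x")]
    for c in cols:
        ax_s.plot(schoenfeld["time"], schoenfeld[c], ".", ms=3, alpha=0.5, label=c)
    ax_s.axhline(0, color="0.6", lw=0.8)
    ax_s.set_xlabel("event time (days)")
    ax_s.set_ylabel("scaled Schoenfeld residual")
    ax_d.plot(np.arange(len(deviance)), deviance, ".", ms=2, alpha=0.4)
    for y in (-2, 2):
        ax_d.axhline(y, ls="--", color="0.4")
    ax_d.set_xlabel("observation")
    ax_d.set_ylabel("deviance residual")
    return axes
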