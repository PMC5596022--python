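"""Plot helpers for the foraging analyses.

Each function draws onto a supplied matplotlib Axes (or creates one) and
returns it, so figures compose the usual way. matplotlib is imported
lazily so the analysis stack works headless without a plotting backend.
"""

from __future__ import annotations

import numpy as np

from .leaving import MODEL_NAMES, ModelComparison
from .mvt import GainCurve, IntakeSurface, LookingRateCurve, OptimalResidenceCurve


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_looking_rate(curve: LookingRateCurve, ax=None):
    """Mean fixation rate per bin over the viewing window."""
    ax = _axes(ax)
    ax.plot(curve.bin_start_s, curve.rate, drawstyle="steps-post")
    ax.set_xlabel("time in patch (s)")
    ax.set_ylabel("fixation rate")
    ax.set_ylim(0, 1.05)
    return ax


def plot_gain(gain: GainCurve, ax=None):
    """Cumulative social-value intake g(T)."""
    ax = _axes(ax)
    ax.plot(gain.bin_centers_s, gain.g)
    ax.set_xlabel("time in patch T (s)")
    ax.set_ylabel("g(T) (looking-s per trial)")
    return ax


def plot_intake_surface(surface: IntakeSurface, ax=None):
    """E_n(T, t) per travel time with the per-travel optima marked."""
    ax = _axes(ax)
    for i, travel in enumerate(surface.travel_times_s):
        (line,) = ax.plot(surface.T_s, surface.E[i], label=f"travel {travel:g} s")
        ax.plot(surface.t_star_s[i], surface.e_star[i], "o", color=line.get_color())
    ax.set_xlabel("time in patch T (s)")
    ax.set_ylabel("intake rate $E_n$")
    ax.legend()
    return ax


def plot_optimal_residence(curve: OptimalResidenceCurve, ax=None, display: bool = True):
    """Optimal residence vs travel time with the juice-optimal baseline."""
    ax = _axes(ax)
    values = curve.t_star_display_s if display else curve.t_star_s
    ax.plot(curve.travel_times_s, values, "o-", label="social-value optimum")
    ax.axhline(curve.juice_optimal_s, ls="--", color="gray", label="juice optimum")
    ax.set_xlabel("travel time (s)")
    ax.set_ylabel("patch-residence time (s)")
    ax.legend()
    return ax


def plot_leave_fits(comparison: ModelComparison, travel_time_s: float, ax=None):
    """Observed leave profile with every fitted model's prediction."""
    ax = _axes(ax)
    plotted_observed = False
    for name in MODEL_NAMES:
        res = comparison.fits.get((name, travel_time_s))
        if res is None:
            continue
        t = res.model.t
        if not plotted_observed:
            ax.plot(t, res.model.endog, "k.", label="observed")
            plotted_observed = True
        ax.plot(t, res.fittedvalues, label=name)
    ax.set_xlabel("time in patch (s)")
    ax.set_ylabel("P(leave)")
    ax.set_title(f"travel {travel_time_s:g} s")
    ax.legend(fontsize="small")
    return ax
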