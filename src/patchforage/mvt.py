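"""Marginal-value-theorem analysis of looking behavior.

The social value extracted from a patch is estimated from looking behavior:
the per-bin rate of on-image fixation declines steeply over the first
seconds of viewing, and its cumulative sum (the gain function g(T)) shows
the diminishing returns that drive the MVT optimum. The intake-rate surface
E_n(T, t) = g(T) / (t + T) — value harvested per unit of travel-plus-
residence time — yields, for each travel time t, the optimal residence
T* = argmax_T E_n. MVT's comparative static, that T* increases with travel
time, is tested on behavior with a one-tailed Kendall correlation (tau-b,
since the discrete travel-time schedule guarantees heavy ties) and an OLS
slope of residence on travel time, restricted to residence times within the
first 5 s of viewing where looking behavior is concentrated.

The model's simplifying assumptions (zero search cost, zero travel energy
cost, one effective patch type, constant 400-ms handling time) are recorded
in :class:`MVTAssumptions`; per the printed intake-rate definition the
handling time does not enter the denominator by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import TaskConfig
from .io import FixationTrace, TrialRecord, s_to_ms, trials_to_frame


@dataclass(frozen=True)
class MVTAssumptions:
    """Simplifying assumptions under which E_n reduces to g(T) / (t + T)."""

    search_cost: float = 0.0
    travel_energy_cost: float = 0.0
    single_patch_type: bool = True
    handling_time_s: float = 0.4
    include_handling_in_denominator: bool = False


@dataclass(frozen=True)
class LookingRateCurve:
    """Mean per-bin fixation rate (proportion of each 100-ms bin on image)."""

    bin_start_s: np.ndarray
    rate: np.ndarray
    n_contributing: np.ndarray


@dataclass(frozen=True)
class GainCurve:
    """Cumulative social-value intake g(T) on the bin grid.

    ``g`` is the cumulative mean looking time per contributing trial, in
    seconds of looking — the value units are arbitrary (any proportionality
    constant cancels in the argmax of g/(t+T)).
    """

    bin_start_s: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.g) < -1e-12):
            raise ValueError("gain curve must be nondecreasing")
        if len(self.g) and self.g[0] < 0:
            raise ValueError("gain must be non-negative")

    @property
    def bin_centers_s(self) -> np.ndarray:
        width = self.bin_start_s[1] - self.bin_start_s[0] if len(self.bin_start_s) > 1 else 0.1
        return self.bin_start_s + width / 2.0


@dataclass(frozen=True)
class IntakeSurface:
    """E_n(T, travel) on the (travel, residence-bin) grid with per-travel optima."""

    travel_times_s: np.ndarray
    T_s: np.ndarray  # residence grid (bin centers)
    E: np.ndarray  # shape (n_travel, n_bins)
    t_star_s: np.ndarray  # per-travel argmax residence
    e_star: np.ndarray  # per-travel maximum intake rate


def _bin_looking(
    fixations: Sequence[FixationTrace],
    config: TaskConfig,
    residences_ms: "dict[tuple, int] | None" = None,
    clip_to_full_bins: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin total looking ms across traces and per-bin contributing counts.

    A trace counts toward a bin's denominator only if its trial's residence
    covers the whole bin; with ``clip_to_full_bins`` (the convention for the
    rate and gain curves, which divide by the contributing count) looking
    time in the trailing partially-covered bin is dropped as well, so rates
    stay proportions of fully observed bins. With ``clip_to_full_bins``
    False all looking time is summed wherever it occurred (the convention
    for the summed value profile, which has no per-bin denominator).
    Without residence information every trace is assumed to span the full
    viewing window.
    """
    n_bins = config.n_bins
    bin_ms = s_to_ms(config.bin_width_s)
    total = np.zeros(n_bins)
    contributing = np.zeros(n_bins)
    window_ms = n_bins * bin_ms
    for trace in fixations:
        residence_ms = window_ms
        if residences_ms is not None:
            residence_ms = residences_ms.get(trace.trial_key, window_ms)
        n_full = min(n_bins, residence_ms // bin_ms)
        contributing[:n_full] += 1
        last_allowed = n_full - 1 if clip_to_full_bins else n_bins - 1
        for start, end in trace.intervals:
            first, last = start // bin_ms, (min(end, window_ms) - 1) // bin_ms
            for b in range(first, min(last, last_allowed) + 1):
                lo, hi = b * bin_ms, (b + 1) * bin_ms
                total[b] += min(end, hi) - max(start, lo)
    return total, contributing


def _residence_map(trials: "Sequence[TrialRecord] | None") -> "dict[tuple, int] | None":
    if trials is None:
        return None
    return {t.key: s_to_ms(t.residence_time_s) for t in trials}


def looking_rate_curve(
    fixations: Sequence[FixationTrace],
    config: TaskConfig | None = None,
    trials: "Sequence[TrialRecord] | None" = None,
) -> LookingRateCurve:
    """Mean fixation rate per 100-ms bin across trials.

    rate(bin) = total on-image ms in the bin across contributing trials
    divided by (n_contributing x bin width); bins beyond a trial's residence
    neither add looking time nor count toward n_contributing.
    """
    config = config or TaskConfig()
    if not fixations:
        raise ValueError("looking_rate_curve requires at least one fixation trace")
    total, contributing = _bin_looking(fixations, config, _residence_map(trials))
    bin_ms = s_to_ms(config.bin_width_s)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(contributing > 0, total / (contributing * bin_ms), 0.0)
    starts = np.arange(config.n_bins) * config.bin_width_s
    return LookingRateCurve(starts, rate, contributing)


def gain_function(
    fixations: Sequence[FixationTrace],
    config: TaskConfig | None = None,
    trials: "Sequence[TrialRecord] | None" = None,
) -> GainCurve:
    """Cumulative gain g(T): running sum of per-bin mean looking time.

    Each bin contributes its mean on-image time per contributing trial
    (seconds); the cumulative sum is nondecreasing by construction and
    estimates the expected total looking time a trial accumulates by
    residence T. With per-trial averaging the estimate does not change under
    replication of the trial set.
    """
    config = config or TaskConfig()
    if not fixations:
        raise ValueError("gain_function requires at least one fixation trace")
    total, contributing = _bin_looking(fixations, config, _residence_map(trials))
    with np.errstate(invalid="ignore", divide="ignore"):
        per_trial_s = np.where(contributing > 0, total / contributing, 0.0) / 1000.0
    starts = np.arange(config.n_bins) * config.bin_width_s
    return GainCurve(starts, np.cumsum(per_trial_s))


def intake_rate_surface(
    gain: GainCurve,
    travel_times_s: Sequence[float],
    config: TaskConfig | None = None,
    assumptions: MVTAssumptions | None = None,
) -> IntakeSurface:
    """E_n(T, t) = g(T) / (t + T) on the bin grid, with per-travel optima.

    T is the bin center; ties in the argmax resolve to the smallest T.
    When ``assumptions.include_handling_in_denominator`` is set the constant
    handling time is added to the denominator (off by default, matching the
    intake-rate definition used throughout).
    """
    config = config or TaskConfig()
    assumptions = assumptions or MVTAssumptions(handling_time_s=config.handling_time_s)
    travels = np.asarray(sorted(travel_times_s), dtype=float)
    if np.any(travels <= 0):
        raise ValueError("travel times must be positive")
    T = gain.bin_centers_s
    denom_extra = assumptions.handling_time_s if assumptions.include_handling_in_denominator else 0.0
    E = gain.g[None, :] / (travels[:, None] + denom_extra + T[None, :])
    idx = np.argmax(E, axis=1)  # argmax returns the first (smallest-T) maximum
    return IntakeSurface(travels, T, E, T[idx], E[np.arange(len(travels)), idx])


@dataclass(frozen=True)
class OptimalResidenceCurve:
    """Predicted residence per travel time, raw and display-offset.

    ``t_star_display_s`` adds the saccade reaction/movement allowance used
    when overlaying predictions on behavior; ``juice_optimal_s`` is the
    travel-independent residence of a juice-maximising forager (minimum
    travel-bar fixation plus the same allowance).
    """

    travel_times_s: np.ndarray
    t_star_s: np.ndarray
    t_star_display_s: np.ndarray
    juice_optimal_s: float


def optimal_residence_curve(
    surface: IntakeSurface, config: TaskConfig | None = None
) -> OptimalResidenceCurve:
    config = config or TaskConfig()
    offset = config.saccade_offset_ms / 1000.0
    juice = (config.min_leave_fixation_ms + config.saccade_offset_ms) / 1000.0
    return OptimalResidenceCurve(
        surface.travel_times_s,
        surface.t_star_s,
        surface.t_star_s + offset,
        juice,
    )


@dataclass(frozen=True)
class MVTTestResult:
    """One-tailed Kendall test and OLS slope of residence on travel time."""

    tau: float
    pvalue: float
    slope: float
    slope_pvalue: float
    n: int


def residence_vs_travel_test(
    trials: "Sequence[TrialRecord] | pd.DataFrame",
    config: TaskConfig | None = None,
) -> MVTTestResult:
    """Test MVT's prediction that residence time rises with travel time.

    Restricted to patch-leaving decisions (timeouts excluded) with residence
    within the analysis window (0-5 s by default). Kendall's tau-b with tie
    correction, one-tailed for positive association; the slope is ordinary
    least squares of residence on travel time (two-sided p).
    """
    config = config or TaskConfig()
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    included = df[df["left_by_choice"] & (df["residence_time_s"] <= config.analysis_window_s)]
    if len(included) < 10:
        raise ValueError(
            f"residence_vs_travel_test needs >= 10 qualifying patch-leaving "
            f"decisions, got {len(included)}"
        )
    travel = included["travel_time_s"].to_numpy(dtype=float)
    residence = included["residence_time_s"].to_numpy(dtype=float)
    if np.all(travel == travel[0]):
        raise ValueError("Kendall tau undefined: all travel times identical")
    tau_res = stats.kendalltau(travel, residence, alternative="greater")
    ols = stats.linregress(travel, residence)
    return MVTTestResult(
        float(tau_res.statistic),
        float(tau_res.pvalue),
        float(ols.slope),
        float(ols.pvalue),
        int(len(included)),
    )
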