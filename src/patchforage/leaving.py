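"""Patch-leaving probability models and their comparison.

Patch-leaving behavior is summarised as a leave-probability profile: the
proportion of patch-leaving decisions falling in each 100-ms bin of the
0-5 s analysis window, built separately per travel time. The instantaneous
social value r(t) is the looking-value profile: on-image looking time
summed over trials per bin, normalized to a maximum of 1.

Four models of the per-bin leave probability are compared:

====================  ===============================================  ===
model                 P_leave(bin)                                       K
====================  ===============================================  ===
``value_and_time``    b0 + b1*r + b2*t + b3*t^2                          4
``time_only``         b0 + b1*t + b2*t^2                                 3
``value_only``        b0 + b1*r                                          2
``hyperbolic``        r / (1 + k*travel)                                 2
====================  ===============================================  ===

where t is the bin-center time in the patch (seconds) and, in the
hyperbolic delay-discounting model, the discount delay is the travel time
to the next patch. Linear models are fitted by ordinary least squares;
the hyperbolic discount parameter k >= 0 maximises the same Gaussian
likelihood. The log-likelihood is the Gaussian density with
maximum-likelihood variance, LL = -(n/2) * (ln(2*pi*sigma^2) + 1) with
sigma^2 = RSS/n; the residual variance is not counted in K for the linear
models, while the hyperbolic K counts the discount parameter plus the
residual scale. Models are ranked by AIC = -2*LL + 2*K, Akaike weights
w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2), and pairwise relative
likelihoods w_i / w_j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import TaskConfig
from .io import FixationTrace, TrialRecord, s_to_ms, trials_to_frame
from .mvt import _bin_looking, _residence_map

logger = logging.getLogger("patchforage.leaving")

MODEL_NAMES = ("value_and_time", "time_only", "value_only", "hyperbolic")
N_FREE_PARAMS = {"value_and_time": 4, "time_only": 3, "value_only": 2, "hyperbolic": 2}

#: Cap on the fitted discount parameter; reaching it means the profile is
#: anti-correlated with the value profile and k is unidentifiable.
K_MAX = 1e6


class FitError(RuntimeError):
    """A model could not be fitted (rank-deficient design, degenerate profile)."""


@dataclass(frozen=True)
class LeaveProfile:
    """Per-bin leave probability at one travel time.

    ``p_leave[b]`` = (leave decisions in bin b) / ``n_trials`` where
    ``n_trials`` counts all patch-leaving trials at this travel time;
    decisions after the analysis window contribute to the denominator only,
    so the profile mass is (included / total) <= 1.
    """

    travel_time_s: float
    bin_start_s: np.ndarray
    p_leave: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        if np.any(self.p_leave < 0) or self.p_leave.sum() > 1.0 + 1e-9:
            raise ValueError("leave profile must be non-negative with total mass <= 1")


@dataclass(frozen=True)
class ValueProfile:
    """Normalized per-bin looking value r(t) with max r = 1."""

    bin_start_s: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.r < 0):
            raise ValueError("value profile must be non-negative")
        if abs(float(self.r.max()) - 1.0) > 1e-9:
            raise ValueError("value profile must be normalized to max 1")


def leave_probability_profile(
    trials: "Sequence[TrialRecord] | pd.DataFrame",
    travel_time_s: float,
    config: TaskConfig | None = None,
) -> LeaveProfile:
    """Bin the patch-leaving decisions at one travel time into 100-ms bins.

    Timeout trials are excluded entirely; leave decisions at or beyond the
    analysis window are excluded from the bins but retained in the
    denominator.
    """
    config = config or TaskConfig()
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    at_travel = df[df["left_by_choice"] & np.isclose(df["travel_time_s"], travel_time_s)]
    residences = at_travel["residence_time_s"].to_numpy(dtype=float)
    included = residences[residences < config.analysis_window_s]
    if len(included) == 0:
        raise ValueError(
            f"no patch-leaving decisions within the analysis window at travel "
            f"time {travel_time_s} s"
        )
    n_bins = config.n_analysis_bins
    idx = np.floor(included / config.bin_width_s).astype(int)
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    starts = np.arange(n_bins) * config.bin_width_s
    return LeaveProfile(float(travel_time_s), starts, counts / len(residences), int(len(residences)))


def value_profile(
    fixations: Sequence[FixationTrace],
    config: TaskConfig | None = None,
    trials: "Sequence[TrialRecord] | None" = None,
) -> ValueProfile:
    """Summed per-bin looking time across trials, normalized to max 1.

    All looking time is summed wherever it occurred (a trace cannot look
    beyond its trial's residence, so no residence clipping is involved);
    the ``trials`` argument is accepted for interface symmetry with the
    rate and gain estimators but does not affect the sum.
    """
    config = config or TaskConfig()
    if not fixations:
        raise ValueError("value_profile requires at least one fixation trace")
    total, _ = _bin_looking(fixations, config, None, clip_to_full_bins=False)
    total = total[: config.n_analysis_bins]
    if total.max() == 0:
        raise ValueError("value_profile undefined: no looking time in the analysis window")
    starts = np.arange(config.n_analysis_bins) * config.bin_width_s
    return ValueProfile(starts, total / total.max())


def aic(ll: float, k: int) -> float:
    """Akaike information criterion, AIC = -2*LL + 2*K."""
    if k < 0 or int(k) != k:
        raise ValueError("K must be a non-negative integer")
    return -2.0 * ll + 2.0 * k


def akaike_weights(aics: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """AIC differences and Akaike weights.

    dAIC_i = AIC_i - min(AIC); w_i = exp(-dAIC_i/2) normalized to sum 1.
    """
    arr = np.asarray(aics, dtype=float)
    if len(arr) == 0 or not np.all(np.isfinite(arr)):
        raise ValueError("akaike_weights requires at least one finite AIC")
    daic = arr - arr.min()
    w = np.exp(-daic / 2.0)
    return daic, w / w.sum()


def relative_likelihoods(weights: Sequence[float]) -> np.ndarray:
    """Pairwise ratio matrix R[i, j] = w_i / w_j (inf where w_j = 0)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = w[:, None] / w[None, :]
    if np.any(w == 0):
        logger.warning("zero Akaike weight: relative likelihoods contain inf/nan")
    return ratio


def _gaussian_ll(resid: np.ndarray) -> float:
    """Gaussian log-likelihood with ML variance sigma^2 = RSS/n."""
    n = len(resid)
    rss = float(resid @ resid)
    if rss <= 0.0:
        return np.inf  # exact interpolation: unbounded likelihood
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


class PatchLeavingModel:
    """One patch-leaving model bound to a leave profile and value profile.

    Parameters
    ----------
    profile
        Leave-probability profile at a single travel time.
    value
        Normalized looking-value profile on the same bin grid.
    variant
        One of ``value_and_time``, ``time_only``, ``value_only``,
        ``hyperbolic``.
    config
        Task configuration (bin width, analysis window).

    ``fit()`` returns a :class:`PatchLeavingResults`.
    """

    def __init__(
        self,
        profile: LeaveProfile,
        value: ValueProfile,
        variant: str,
        config: TaskConfig | None = None,
    ):
        if variant not in MODEL_NAMES:
            raise ValueError(f"unknown model variant {variant!r}; expected one of {MODEL_NAMES}")
        if len(profile.p_leave) != len(value.r):
            raise ValueError("leave profile and value profile must share the bin grid")
        self.profile = profile
        self.value = value
        self.variant = variant
        self.config = config or TaskConfig()
        self.t = profile.bin_start_s + self.config.bin_width_s / 2.0  # bin centers
        self.endog = profile.p_leave

    @classmethod
    def from_trials(
        cls,
        trials: "Sequence[TrialRecord] | pd.DataFrame",
        fixations: Sequence[FixationTrace],
        travel_time_s: float,
        variant: str,
        config: TaskConfig | None = None,
        value: ValueProfile | None = None,
    ) -> "PatchLeavingModel":
        """Build the model directly from trial and fixation tables."""
        config = config or TaskConfig()
        profile = leave_probability_profile(trials, travel_time_s, config)
        if value is None:
            trial_list = trials if not isinstance(trials, pd.DataFrame) else None
            value = value_profile(fixations, config, trials=trial_list)
        return cls(profile, value, variant, config)

    def _design(self) -> "tuple[np.ndarray, tuple[str, ...]]":
        r, t = self.value.r, self.t
        if self.variant == "value_and_time":
            return np.column_stack([np.ones_like(t), r, t, t**2]), ("b0", "b1", "b2", "b3")
        if self.variant == "time_only":
            return np.column_stack([np.ones_like(t), t, t**2]), ("b0", "b1", "b2")
        if self.variant == "value_only":
            return np.column_stack([np.ones_like(t), r]), ("b0", "b1")
        raise AssertionError(self.variant)

    def fit(self) -> "PatchLeavingResults":
        if self.variant == "hyperbolic":
            return self._fit_hyperbolic()
        X, names = self._design()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise FitError(
                f"{self.variant}: rank-deficient design (is the value profile constant?)"
            )
        ols = sm.OLS(self.endog, X).fit()
        fitted = np.asarray(ols.fittedvalues)
        resid = self.endog - fitted
        ll = _gaussian_ll(resid)
        k = N_FREE_PARAMS[self.variant]
        return PatchLeavingResults(
            model=self,
            params=dict(zip(names, np.asarray(ols.params))),
            llf=ll,
            k=k,
            aic=aic(ll, k),
            rmse=float(np.sqrt(np.mean(resid**2))),
            fittedvalues=fitted,
        )

    def _fit_hyperbolic(self) -> "PatchLeavingResults":
        """Exact maximizer of the Gaussian likelihood over k >= 0.

        With travel fixed, the prediction r/(1 + k*travel) = c*r is linear in
        c = 1/(1 + k*travel), so the RSS-minimizing c has the closed form
        sum(p*r)/sum(r^2); the bound k >= 0 clips c to (0, 1].
        """
        r, p = self.value.r, self.endog
        travel = self.profile.travel_time_s
        denom = float(r @ r)
        if denom == 0.0:
            raise FitError("hyperbolic: value profile is identically zero")
        c_hat = float(p @ r) / denom
        if c_hat >= 1.0:
            k_hat = 0.0
        elif c_hat <= 0.0:
            k_hat = K_MAX
            logger.warning(
                "hyperbolic: profile anti-correlated with value; k capped at %g", K_MAX
            )
        else:
            k_hat = (1.0 / c_hat - 1.0) / travel
        fitted = r / (1.0 + k_hat * travel)
        resid = p - fitted
        ll = _gaussian_ll(resid)
        k_params = N_FREE_PARAMS["hyperbolic"]
        return PatchLeavingResults(
            model=self,
            params={"k": k_hat},
            llf=ll,
            k=k_params,
            aic=aic(ll, k_params),
            rmse=float(np.sqrt(np.mean(resid**2))),
            fittedvalues=fitted,
        )


@dataclass
class PatchLeavingResults:
    """Fit of one patch-leaving model at one travel time."""

    model: PatchLeavingModel
    params: dict
    llf: float
    k: int
    aic: float
    rmse: float
    fittedvalues: np.ndarray

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    def summary(self) -> str:
        lines = [
            f"Patch-leaving model: {self.model.variant}",
            f"travel time: {self.model.profile.travel_time_s:g} s   "
            f"bins: {self.nobs}   trials: {self.model.profile.n_trials}",
            f"LL = {self.llf:.3f}   K = {self.k}   AIC = {self.aic:.3f}   "
            f"RMSE = {self.rmse:.4f}",
            "coefficients:",
        ]
        lines += [f"  {name:>3s} = {val: .6g}" for name, val in self.params.items()]
        return "\n".join(lines)


@dataclass
class ModelComparison:
    """Per-travel-time comparison of the four patch-leaving models.

    ``table`` has one row per (model, travel) with columns
    model, travel, LL, K, AIC, dAIC, w, RMSE; ``ratios[travel]`` holds the
    pairwise relative-likelihood matrix in :data:`MODEL_NAMES` order;
    ``fits[(model, travel)]`` retains the individual results.
    """

    table: pd.DataFrame
    ratios: dict
    fits: dict
    errors: dict = field(default_factory=dict)

    def weights(self, travel_time_s: float) -> pd.Series:
        sub = self.table[np.isclose(self.table["travel"], travel_time_s)]
        return sub.set_index("model")["w"]

    def best_model(self, travel_time_s: float) -> str:
        return str(self.weights(travel_time_s).idxmax())

    def total_aic(self) -> pd.Series:
        """Summed AIC per model across travel times (joint ranking)."""
        return self.table.groupby("model", sort=False)["AIC"].sum()

    def summary(self) -> str:
        out = ["Patch-leaving model comparison (per travel time)", ""]
        out.append(
            self.table.to_string(
                index=False,
                formatters={
                    "LL": "{:.3f}".format,
                    "AIC": "{:.3f}".format,
                    "dAIC": "{:.3f}".format,
                    "w": "{:.3g}".format,
                    "RMSE": "{:.4f}".format,
                },
            )
        )
        if self.errors:
            out.append("")
            out += [f"failed fits: {key}: {msg}" for key, msg in self.errors.items()]
        return "\n".join(out)


def compare_models(
    trials: "Sequence[TrialRecord] | pd.DataFrame",
    fixations: Sequence[FixationTrace],
    config: TaskConfig | None = None,
    travel_times_s: "Sequence[float] | None" = None,
) -> ModelComparison:
    """Fit all four models at each travel time and rank them.

    The value profile is shared across travel times (looking behavior is
    pooled over all trials); the leave profile is rebuilt per travel time.
    Fit failures are annotated and the remaining models still compared.
    """
    config = config or TaskConfig()
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    travels = tuple(travel_times_s) if travel_times_s is not None else config.travel_times_s
    trial_list = None if isinstance(trials, pd.DataFrame) else trials
    value = value_profile(fixations, config, trials=trial_list)

    rows, ratios, fits, errors = [], {}, {}, {}
    for travel in travels:
        profile = leave_probability_profile(df, travel, config)
        results = {}
        for name in MODEL_NAMES:
            try:
                results[name] = PatchLeavingModel(profile, value, name, config).fit()
            except FitError as exc:
                errors[(name, travel)] = str(exc)
                logger.warning("fit failed for %s at travel %g: %s", name, travel, exc)
        if not results:
            continue
        names = [n for n in MODEL_NAMES if n in results]
        daic, w = akaike_weights([results[n].aic for n in names])
        ratios[travel] = relative_likelihoods(w)
        for name, d, wi in zip(names, daic, w):
            res = results[name]
            fits[(name, travel)] = res
            rows.append(
                {
                    "model": name,
                    "travel": travel,
                    "LL": res.llf,
                    "K": res.k,
                    "AIC": res.aic,
                    "dAIC": float(d),
                    "w": float(wi),
                    "RMSE": res.rmse,
                }
            )
    if not rows:
        raise ValueError("no model could be fitted at any travel time")
    table = pd.DataFrame(rows, columns=["model", "travel", "LL", "K", "AIC", "dAIC", "w", "RMSE"])
    return ModelComparison(table, ratios, fits, errors)
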