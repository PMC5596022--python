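"""Patch-type preference statistics.

The preference index is the contrast ratio CR = (F_A - F_B) / (F_A + F_B)
over selection counts. Following the task's convention, F_A counts
selections of *non-negative* images in the two valence environments and of
*social* (intact face) images in the social/nonsocial environment; F_B
counts the complementary type. Note that in the trial tables the symbolic
``patch_type`` 'A' denotes the negative patch in valence environments, so
there F_A counts patch_type 'B'.

Alongside the CR the module provides the choice-order curves (cumulative
proportion of each patch type selected as a function of choice number), a
one-sample t-test on daily CRs, a chi-squared test on first choices, a
Kolmogorov-Smirnov test on the choice-order distributions, and a Wilcoxon
test on per-trial looking times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FixationTrace, TrialRecord, trials_to_frame

logger = logging.getLogger("patchforage.preference")

#: patch_type whose selections count toward F_A, per environment type.
F_A_PATCH_TYPE = {
    "color_valence": "B",  # F_A = non-negative images = symbolic type B
    "fractal_valence": "B",
    "social_nonsocial": "A",  # F_A = social (intact face) images = type A
}


def _as_frame(trials: "Sequence[TrialRecord] | pd.DataFrame") -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return trials_to_frame(trials)


def contrast_ratio(f_a: int, f_b: int) -> float:
    """(F_A - F_B) / (F_A + F_B); undefined when both counts are zero."""
    if f_a < 0 or f_b < 0:
        raise ValueError("selection counts must be non-negative")
    if f_a + f_b == 0:
        raise ValueError("contrast ratio undefined: both selection counts are zero")
    return (f_a - f_b) / (f_a + f_b)


@dataclass(frozen=True)
class PreferenceSummary:
    """Selection counts and contrast ratio for one (session, environment type)."""

    session_id: str
    environment_type: str
    f_a: int
    f_b: int
    cr: float


def daily_contrast_ratios(
    trials: "Sequence[TrialRecord] | pd.DataFrame",
) -> list[PreferenceSummary]:
    """One contrast ratio per (session, environment_type).

    F_A/F_B follow the environment-specific semantics in
    :data:`F_A_PATCH_TYPE`. Groups with zero selections are skipped with a
    logged warning.
    """
    df = _as_frame(trials)
    if not len(df):
        raise ValueError("daily_contrast_ratios requires a non-empty trial table")
    summaries: list[PreferenceSummary] = []
    for (session_id, env_type), grp in df.groupby(
        ["session_id", "environment_type"], sort=True
    ):
        a_type = F_A_PATCH_TYPE[env_type]
        f_a = int((grp["patch_type"] == a_type).sum())
        f_b = int((grp["patch_type"] != a_type).sum())
        if f_a + f_b == 0:  # pragma: no cover - empty group cannot arise from groupby
            logger.warning("skipping (%s, %s): zero selections", session_id, env_type)
            continue
        summaries.append(
            PreferenceSummary(str(session_id), str(env_type), f_a, f_b, contrast_ratio(f_a, f_b))
        )
    return summaries


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: int


def preference_t_test(daily_crs: Iterable[float]) -> TTestResult:
    """Two-tailed one-sample t-test of the daily contrast ratios against 0.

    A zero-variance sample with nonzero mean is reported as infinite t with
    p = 0 (logged); zero variance at zero mean gives t = 0, p = 1.
    """
    crs = np.asarray(list(daily_crs), dtype=float)
    if len(crs) < 2:
        raise ValueError("preference_t_test requires at least two daily contrast ratios")
    if np.std(crs, ddof=1) == 0.0:
        mean = float(np.mean(crs))
        if mean == 0.0:
            return TTestResult(0.0, 1.0, len(crs) - 1)
        logger.warning("zero-variance contrast ratios with nonzero mean %.3g", mean)
        return TTestResult(float(np.sign(mean)) * np.inf, 0.0, len(crs) - 1)
    t, p = stats.ttest_1samp(crs, 0.0)
    return TTestResult(float(t), float(p), len(crs) - 1)


@dataclass(frozen=True)
class ChoiceOrderCurve:
    """Mean cumulative proportion of one patch type selected by choice number.

    ``proportions[k-1]`` is the mean over environments of (patches of this
    type selected within the first k choices) / (patches of this type
    available, i.e. 4). ``per_environment`` retains the individual curves
    (environments x 8) for distributional tests.
    """

    patch_type: str
    choice_numbers: tuple[int, ...]
    proportions: np.ndarray
    per_environment: np.ndarray


def choice_order_curves(
    trials: "Sequence[TrialRecord] | pd.DataFrame",
    n_per_type: int = 4,
) -> tuple[ChoiceOrderCurve, ChoiceOrderCurve]:
    """Cumulative selection curves for patch types A and B.

    Only environments in which all ``2 * n_per_type`` patches were visited
    enter the curves; malformed or truncated environments are excluded with
    a logged warning (their later choice numbers are undefined).
    """
    df = _as_frame(trials)
    n_choices = 2 * n_per_type
    rows_a, rows_b = [], []
    for (session_id, env_index), grp in df.groupby(["session_id", "environment_index"]):
        grp = grp.sort_values("choice_index")
        if len(grp) != n_choices or (grp["patch_type"] == "A").sum() != n_per_type:
            logger.warning(
                "excluding environment (%s, %s): %d choices (expected %d)",
                session_id, env_index, len(grp), n_choices,
            )
            continue
        is_a = (grp["patch_type"].to_numpy() == "A").astype(float)
        rows_a.append(np.cumsum(is_a) / n_per_type)
        rows_b.append(np.cumsum(1.0 - is_a) / n_per_type)
    if not rows_a:
        raise ValueError("no complete environments available for choice-order curves")
    per_a, per_b = np.vstack(rows_a), np.vstack(rows_b)
    numbers = tuple(range(1, n_choices + 1))
    return (
        ChoiceOrderCurve("A", numbers, per_a.mean(axis=0), per_a),
        ChoiceOrderCurve("B", numbers, per_b.mean(axis=0), per_b),
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    pvalue: float
    df: int
    counts: tuple[int, int]


def first_choice_chisq(trials: "Sequence[TrialRecord] | pd.DataFrame") -> ChiSquareResult:
    """Pearson chi-squared test of first-choice type counts against 50/50.

    The first choice of every environment is pooled; no continuity
    correction is applied.
    """
    df = _as_frame(trials)
    firsts = df[df["choice_index"] == 1]
    if not len(firsts):
        raise ValueError("no first choices found")
    n_a = int((firsts["patch_type"] == "A").sum())
    n_b = int(len(firsts) - n_a)
    chi2, p = stats.chisquare([n_a, n_b])
    return ChiSquareResult(float(chi2), float(p), 1, (n_a, n_b))


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float


def choice_order_ks(curve_a: ChoiceOrderCurve, curve_b: ChoiceOrderCurve) -> KSResult:
    """Two-sample KS test on the pooled per-environment cumulative proportions.

    Compares the distribution of per-environment cumulative proportions of
    type A against type B (pooled over environments and choice numbers). A
    positive shift of one distribution indicates that type's patches were
    explored earlier.
    """
    sample_a = curve_a.per_environment.ravel()
    sample_b = curve_b.per_environment.ravel()
    if np.array_equal(np.sort(sample_a), np.sort(sample_b)):
        return KSResult(0.0, 1.0)
    d, p = stats.ks_2samp(sample_a, sample_b)
    return KSResult(float(d), float(p))


@dataclass(frozen=True)
class LookingTimeResult:
    statistic: float
    pvalue: float
    method: str
    mean_ms: dict
    sem_ms: dict
    n: dict


def looking_time_test(
    trials: "Sequence[TrialRecord] | pd.DataFrame",
    fixations: Sequence[FixationTrace],
    method: str = "signed_rank",
) -> LookingTimeResult:
    """Rank test of per-trial total looking time between the two patch types.

    ``signed_rank`` (default) pairs per-session mean looking times of the
    two types (Wilcoxon signed-rank, as looking times are not normally
    distributed); ``rank_sum`` compares the raw per-trial totals
    (Mann-Whitney U). Per-type means and standard errors of the per-trial
    totals are reported either way.
    """
    df = _as_frame(trials)
    look = {t.trial_key: t.total_looking_ms for t in fixations}
    df = df.assign(
        looking_ms=[
            look.get((r.session_id, r.environment_index, r.choice_index), 0)
            for r in df.itertuples(index=False)
        ]
    )
    by_type = {pt: grp["looking_ms"].to_numpy(dtype=float) for pt, grp in df.groupby("patch_type")}
    if set(by_type) != {"A", "B"}:
        raise ValueError("looking_time_test requires trials of both patch types")
    mean_ms = {pt: float(np.mean(v)) for pt, v in by_type.items()}
    sem_ms = {pt: float(stats.sem(v)) if len(v) > 1 else float("nan") for pt, v in by_type.items()}
    n = {pt: int(len(v)) for pt, v in by_type.items()}

    if method == "signed_rank":
        per_session = df.groupby(["session_id", "patch_type"])["looking_ms"].mean().unstack()
        paired = per_session.dropna()
        if len(paired) < 2:
            raise ValueError("signed_rank needs >= 2 sessions with both patch types")
        diffs = paired["A"].to_numpy() - paired["B"].to_numpy()
        if np.all(diffs == 0):
            logger.warning("all per-session differences are zero; reporting p = 1")
            return LookingTimeResult(0.0, 1.0, method, mean_ms, sem_ms, n)
        stat, p = stats.wilcoxon(paired["A"], paired["B"])
    elif method == "rank_sum":
        stat, p = stats.mannwhitneyu(by_type["A"], by_type["B"], alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}; use 'signed_rank' or 'rank_sum'")
    return LookingTimeResult(float(stat), float(p), method, mean_ms, sem_ms, n)
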