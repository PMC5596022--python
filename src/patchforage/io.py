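"""Trial and fixation tables: domain types, CSV/TSV round-trip, validation.

Two plain-text tables carry a foraging dataset:

``trials`` — one row per patch visit with columns
``session_id, subject_id, environment_type, environment_index, choice_index,
patch_type, travel_time_s, residence_time_s, left_by_choice``.

``fixations`` — one row per on-image looking interval with columns
``session_id, environment_index, choice_index, start_ms, end_ms``; intervals
are half-open ``[start, end)`` in integer milliseconds from image onset.

Times are seconds (float) in the trial table and integer milliseconds in the
fixation table; :func:`ms_to_s` / :func:`s_to_ms` centralise the conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import TaskConfig

ENVIRONMENT_TYPES = ("color_valence", "fractal_valence", "social_nonsocial")
PATCH_TYPES = ("A", "B")

TRIAL_COLUMNS = (
    "session_id",
    "subject_id",
    "environment_type",
    "environment_index",
    "choice_index",
    "patch_type",
    "travel_time_s",
    "residence_time_s",
    "left_by_choice",
)
FIXATION_COLUMNS = ("session_id", "environment_index", "choice_index", "start_ms", "end_ms")


class FormatError(ValueError):
    """The file is not the documented delimited table (missing/unknown column)."""


class ValidationError(ValueError):
    """A row violates a domain invariant."""


def ms_to_s(ms: float) -> float:
    return ms / 1000.0


def s_to_ms(s: float) -> int:
    return int(round(s * 1000.0))


@dataclass(frozen=True)
class TrialRecord:
    """One patch visit.

    ``patch_type`` is symbolic: within valence environments A is the
    negative-expression patch and B the non-negative one; in the
    social/nonsocial environment A is the social (intact face) patch and B
    the scrambled-face patch.
    """

    session_id: str
    subject_id: str
    environment_type: str
    environment_index: int
    choice_index: int
    patch_type: str
    travel_time_s: float
    residence_time_s: float
    left_by_choice: bool

    def __post_init__(self) -> None:
        if self.environment_type not in ENVIRONMENT_TYPES:
            raise ValidationError(
                f"environment_type must be one of {ENVIRONMENT_TYPES}, got {self.environment_type!r}"
            )
        if self.patch_type not in PATCH_TYPES:
            raise ValidationError(f"patch_type must be 'A' or 'B', got {self.patch_type!r}")
        if self.environment_index < 0:
            raise ValidationError("environment_index must be >= 0")
        if not 1 <= self.choice_index <= 8:
            raise ValidationError(f"choice_index must be in 1..8, got {self.choice_index}")
        if not self.travel_time_s > 0:
            raise ValidationError("travel_time_s must be > 0")
        if self.residence_time_s < 0:
            raise ValidationError("residence_time_s must be >= 0")

    @property
    def key(self) -> tuple[str, int, int]:
        """Key joining a trial to its fixation trace."""
        return (self.session_id, self.environment_index, self.choice_index)


@dataclass(frozen=True)
class FixationTrace:
    """On-image looking intervals for one trial.

    ``intervals`` are half-open ``[start, end)`` ms from image onset, sorted
    and non-overlapping (adjacent intervals are merged on construction).
    """

    trial_key: tuple[str, int, int]
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", merge_intervals(self.intervals))
        for start, end in self.intervals:
            if start < 0 or end > 15000:
                raise ValidationError(
                    f"interval ({start}, {end}) outside [0, 15000] ms for trial {self.trial_key}"
                )

    @property
    def total_looking_ms(self) -> int:
        return sum(end - start for start, end in self.intervals)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort half-open intervals, merge adjacent ones, reject overlap/inversion."""
    ivals = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivals:
        if end <= start:
            raise ValidationError(f"interval ({start}, {end}) has end <= start")
        if merged and start < merged[-1][1]:
            raise ValidationError(
                f"interval ({start}, {end}) overlaps ({merged[-1][0]}, {merged[-1][1]})"
            )
        if merged and start == merged[-1][1]:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return tuple(merged)


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise FormatError(f"{path}: unknown column(s) {unknown}")


def read_trials(path: str | Path, config: TaskConfig | None = None) -> list[TrialRecord]:
    """Read and validate a trial table (comma or tab delimited)."""
    config = config or TaskConfig()
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    _check_columns(df, TRIAL_COLUMNS, path)
    trials: list[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            trials.append(
                TrialRecord(
                    session_id=str(row.session_id),
                    subject_id=str(row.subject_id),
                    environment_type=str(row.environment_type),
                    environment_index=int(row.environment_index),
                    choice_index=int(row.choice_index),
                    patch_type=str(row.patch_type),
                    travel_time_s=float(row.travel_time_s),
                    residence_time_s=float(row.residence_time_s),
                    left_by_choice=_parse_bool(row.left_by_choice),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from None
    for i, t in enumerate(trials, start=2):
        if t.residence_time_s > config.viewing_window_s + 1e-9:
            raise ValidationError(
                f"{path}: line {i}: residence_time_s {t.residence_time_s} exceeds "
                f"viewing window {config.viewing_window_s}"
            )
        if not t.left_by_choice and not math.isclose(
            t.residence_time_s, config.viewing_window_s, abs_tol=1e-9
        ):
            raise ValidationError(
                f"{path}: line {i}: timeout trial must have residence_time_s = "
                f"{config.viewing_window_s}, got {t.residence_time_s}"
            )
    seen: dict[tuple, int] = {}
    for i, t in enumerate(trials, start=2):
        if t.key in seen:
            raise ValidationError(
                f"{path}: line {i}: duplicate choice_index {t.choice_index} in "
                f"(session {t.session_id}, environment {t.environment_index})"
            )
        seen[t.key] = i
    return trials


def _parse_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValidationError(f"cannot parse boolean {value!r}")


def write_trials(trials: Iterable[TrialRecord], path: str | Path, sep: str = ",") -> None:
    trials_to_frame(trials).to_csv(path, sep=sep, index=False)


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Trial records as a DataFrame with the canonical column order."""
    rows = [
        {c: getattr(t, c) for c in TRIAL_COLUMNS}
        for t in trials
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def read_fixations(path: str | Path) -> list[FixationTrace]:
    """Read a long-format fixation table and assemble one trace per trial.

    Adjacent intervals are merged; overlaps or inverted intervals raise
    :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    _check_columns(df, FIXATION_COLUMNS, path)
    if len(df) and ((df["start_ms"] < 0).any() or (df["end_ms"] < 0).any()):
        raise ValidationError(f"{path}: interval bounds must be non-negative integers")
    traces: list[FixationTrace] = []
    if not len(df):
        return traces
    grouped = df.groupby(["session_id", "environment_index", "choice_index"], sort=False)
    for (session_id, env_index, choice_index), grp in grouped:
        key = (str(session_id), int(env_index), int(choice_index))
        intervals = list(zip(grp["start_ms"].astype(int), grp["end_ms"].astype(int)))
        try:
            traces.append(FixationTrace(trial_key=key, intervals=tuple(intervals)))
        except ValidationError as exc:
            raise ValidationError(f"{path}: trial {key}: {exc}") from None
    return traces


def write_fixations(traces: Iterable[FixationTrace], path: str | Path, sep: str = ",") -> None:
    fixations_to_frame(traces).to_csv(path, sep=sep, index=False)


def fixations_to_frame(traces: Iterable[FixationTrace]) -> pd.DataFrame:
    rows = []
    for trace in traces:
        session_id, env_index, choice_index = trace.trial_key
        for start, end in trace.intervals:
            rows.append(
                {
                    "session_id": session_id,
                    "environment_index": env_index,
                    "choice_index": choice_index,
                    "start_ms": start,
                    "end_ms": end,
                }
            )
    return pd.DataFrame(rows, columns=list(FIXATION_COLUMNS))


@dataclass
class ValidationReport:
    """Report-only cross-validation of a dataset; never raises."""

    problems: list[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        self.problems.append(message)

    @property
    def ok(self) -> bool:
        return not self.problems

    def __len__(self) -> int:
        return len(self.problems)

    def __str__(self) -> str:
        return "OK" if self.ok else "\n".join(self.problems)


def validate_dataset(
    trials: Sequence[TrialRecord],
    fixations: Sequence[FixationTrace],
    config: TaskConfig | None = None,
) -> ValidationReport:
    """Cross-check trials against fixation traces.

    Lists every violation rather than raising: orphan traces, looking beyond
    the trial's residence time, residence beyond the viewing window,
    timeout trials with residence below the window.
    """
    config = config or TaskConfig()
    report = ValidationReport()
    by_key = {t.key: t for t in trials}
    for t in trials:
        if t.residence_time_s > config.viewing_window_s + 1e-9:
            report.add(
                f"trial {t.key}: residence {t.residence_time_s} s exceeds viewing "
                f"window {config.viewing_window_s} s"
            )
        if not t.left_by_choice and not math.isclose(
            t.residence_time_s, config.viewing_window_s, abs_tol=1e-9
        ):
            report.add(
                f"trial {t.key}: timeout trial with residence {t.residence_time_s} s "
                f"!= viewing window {config.viewing_window_s} s"
            )
    for trace in fixations:
        trial = by_key.get(trace.trial_key)
        if trial is None:
            report.add(f"fixation trace {trace.trial_key}: no matching trial")
            continue
        residence_ms = s_to_ms(trial.residence_time_s)
        for start, end in trace.intervals:
            if end > residence_ms:
                report.add(
                    f"fixation trace {trace.trial_key}: looking interval ({start}, {end}) "
                    f"extends beyond residence time {residence_ms} ms"
                )
    return report
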