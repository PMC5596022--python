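"""Task configuration shared by the generator and every analysis stage.

The defaults encode the foraging-task geometry: a 15-s free-viewing window
per patch visit, a 400-ms handling delay between patch selection and image
onset, travel times drawn from {1, 3, 5, 7} s, a 70-s time budget per
environment, and the 0-5 s analysis window with 100-ms binning used by the
patch-leaving analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the social-information foraging task and its analyses.

    Attributes
    ----------
    viewing_window_s
        Maximum free-viewing time in a patch (seconds).
    handling_time_s
        Fixed delay between patch selection and image onset (seconds).
    travel_times_s
        Set of travel times (seconds) the travel bar can impose.
    environment_timeout_s
        Time budget within one environment before it is closed.
    inter_environment_interval_s
        Pause between environments (bookkeeping only).
    n_patches_per_type
        Patches of each of the two types per environment.
    bin_width_s
        Width of the analysis bins (seconds).
    analysis_window_s
        Residence-time window used by the MVT test and leaving models.
    min_leave_fixation_ms
        Minimum fixation on the travel bar required to leave a patch.
    saccade_offset_ms
        Saccade reaction/movement allowance added when displaying
        theoretical optimal-residence curves.
    """

    viewing_window_s: float = 15.0
    handling_time_s: float = 0.4
    travel_times_s: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    environment_timeout_s: float = 70.0
    inter_environment_interval_s: float = 5.0
    n_patches_per_type: int = 4
    bin_width_s: float = 0.1
    analysis_window_s: float = 5.0
    min_leave_fixation_ms: int = 200
    saccade_offset_ms: int = 250

    def __post_init__(self) -> None:
        positive = [
            ("viewing_window_s", self.viewing_window_s),
            ("handling_time_s", self.handling_time_s),
            ("environment_timeout_s", self.environment_timeout_s),
            ("inter_environment_interval_s", self.inter_environment_interval_s),
            ("n_patches_per_type", self.n_patches_per_type),
            ("bin_width_s", self.bin_width_s),
            ("analysis_window_s", self.analysis_window_s),
            ("min_leave_fixation_ms", self.min_leave_fixation_ms),
            ("saccade_offset_ms", self.saccade_offset_ms),
        ]
        for name, value in positive:
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not self.travel_times_s or any(t <= 0 for t in self.travel_times_s):
            raise ValueError("travel_times_s must be a non-empty set of positive values")
        if self.analysis_window_s > self.viewing_window_s:
            raise ValueError("analysis_window_s must not exceed viewing_window_s")
        object.__setattr__(self, "travel_times_s", tuple(sorted(self.travel_times_s)))

    @property
    def n_bins(self) -> int:
        """Number of bins tiling [0, viewing_window_s)."""
        return int(round(self.viewing_window_s / self.bin_width_s))

    @property
    def n_analysis_bins(self) -> int:
        """Number of bins tiling [0, analysis_window_s)."""
        return int(round(self.analysis_window_s / self.bin_width_s))

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d


def load_config(path: str | Path) -> TaskConfig:
    """Read a flat ``key: value`` config file into a :class:`TaskConfig`.

    Lines are ``key: value`` (or ``key=value``); blank lines and ``#``
    comments are ignored; ``travel_times_s`` is a comma-separated list.
    Unknown keys raise ``ValueError`` so typos do not pass silently.
    """
    known = {f.name: f for f in fields(TaskConfig)}
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sep = ":" if ":" in line else "="
        if sep not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, value = (part.strip() for part in line.split(sep, 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key == "travel_times_s":
            kwargs[key] = tuple(float(v) for v in value.split(","))
        elif key in ("n_patches_per_type", "min_leave_fixation_ms", "saccade_offset_ms"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return TaskConfig(**kwargs)


def save_config(config: TaskConfig, path: str | Path) -> None:
    """Write ``config`` as a flat ``key: value`` file readable by :func:`load_config`."""
    lines = []
    for key, value in config.to_dict().items():
        if isinstance(value, list):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key}: {value}")
    Path(path).write_text("\n".join(lines) + "\n")
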