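"""Synthetic behavioral sessions for the foraging analyses.

The generator emulates the structure of the social-information foraging
task: environments of eight patches (four of each of two types), visited
sequentially under a type preference, each visit imposing a travel time
drawn from the configured set, a free-viewing period of up to 15 s, and an
on-image looking process whose probability declines steeply within the
first ~5 s.

Patch residence is produced by one of four leaving policies:

``hazard``
    Per 100-ms bin, leave with probability
    ``b0 + b1*r(t) + b2*t + b3*t**2`` (clamped to [0, 1]), where ``r(t)`` is
    the normalized looking-value profile — the rate-maximising regression
    form of patch leaving, applied as a bin-wise hazard.
``hyperbolic``
    Per-bin leave probability ``r(t) / (1 + k * travel)`` — hyperbolic
    discounting of the remaining social value by the travel delay.
``mvt_threshold``
    Deterministic optimum ``argmax_T g(T) / (travel + T)`` of the supplied
    gain curve plus Gaussian jitter — an agent that follows the
    marginal-value rule exactly.
``juice_max``
    Leave immediately: the minimum travel-bar fixation plus a saccade
    allowance, constant across travel times (the juice-maximising strategy,
    since the liquid reward is delivered on patch entry regardless of
    looking).

Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .config import TaskConfig
from .io import FixationTrace, TrialRecord, s_to_ms

POLICIES = ("hazard", "mvt_threshold", "hyperbolic", "juice_max")

#: Default bin-wise hazard coefficients (b0, b1, b2, b3). Chosen so that the
#: bulk (~85-90%) of patch-leaving decisions fall within the first 5 s of
#: viewing, the share observed in the task, with genuine contributions from
#: both the value term and the time terms.
DEFAULT_HAZARD_COEFFS = (0.012, 0.06, 0.005, 0.0005)


@dataclass(frozen=True)
class PolicySpec:
    """A named patch-leaving policy with its complete parameter set."""

    name: str
    parameters: dict = field(default_factory=dict)

    REQUIRED = {
        "hazard": ("coeffs", "look_tau_s"),
        "hyperbolic": ("discount_k", "look_tau_s"),
        "mvt_threshold": ("noise_sd_s",),
        "juice_max": (),
    }

    def __post_init__(self) -> None:
        if self.name not in POLICIES:
            raise ValueError(f"unknown policy {self.name!r}; expected one of {POLICIES}")
        missing = [k for k in self.REQUIRED[self.name] if k not in self.parameters]
        if missing:
            raise ValueError(f"policy {self.name!r} missing parameter(s) {missing}")


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic-session generator.

    ``look_p0`` and ``look_tau_s`` shape the looking process: the per-ms
    probability of being on the image is ``look_p0 * exp(-t / look_tau_s)``,
    which reproduces the steep early decline of image fixation. With the
    default 1.3-s decay constant, looking is essentially over by 5 s.
    ``preference_prob_A`` is the probability that the next patch chosen is of
    type A while patches of both types remain.
    """

    n_environments: int = 100
    environment_type: str = "color_valence"
    subject_id: str = "S1"
    environments_per_session: int = 20
    preference_prob_A: float = 0.7
    look_p0: float = 0.9
    look_tau_s: float = 1.3
    policy: str = "hazard"
    hazard_coeffs: tuple[float, float, float, float] = DEFAULT_HAZARD_COEFFS
    discount_k: float = 3.0
    noise_sd_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.preference_prob_A <= 1.0:
            raise ValueError("preference_prob_A must be in [0, 1]")
        if not 0.0 <= self.look_p0 <= 1.0:
            raise ValueError("look_p0 must be in [0, 1]")
        if not self.look_tau_s > 0:
            raise ValueError("look_tau_s must be > 0")
        if self.noise_sd_s < 0:
            raise ValueError("noise_sd_s must be >= 0")
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.n_environments < 1:
            raise ValueError("n_environments must be >= 1")

    def policy_spec(self) -> PolicySpec:
        if self.policy == "hazard":
            params = {"coeffs": self.hazard_coeffs, "look_tau_s": self.look_tau_s}
        elif self.policy == "hyperbolic":
            params = {"discount_k": self.discount_k, "look_tau_s": self.look_tau_s}
        elif self.policy == "mvt_threshold":
            params = {"noise_sd_s": self.noise_sd_s}
        else:
            params = {}
        return PolicySpec(self.policy, params)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hazard_coeffs"] = list(self.hazard_coeffs)
        return d


def looking_probability(t_s: np.ndarray, look_p0: float, look_tau_s: float) -> np.ndarray:
    """Per-ms probability of being on the image at time ``t_s`` (seconds)."""
    t_s = np.asarray(t_s, dtype=float)
    if math.isinf(look_tau_s):
        return np.full_like(t_s, look_p0)
    return look_p0 * np.exp(-t_s / look_tau_s)


def analytic_gain(T_s: np.ndarray, look_p0: float, look_tau_s: float) -> np.ndarray:
    """Expected cumulative looking time (s) by residence ``T_s`` under the generator.

    The integral of the looking probability: ``p0 * tau * (1 - exp(-T/tau))``.
    Serves as the gain function g(T) for the ``mvt_threshold`` policy and as
    the closed form against which the empirical gain estimate is checked.
    """
    T_s = np.asarray(T_s, dtype=float)
    if math.isinf(look_tau_s):
        return look_p0 * T_s
    return look_p0 * look_tau_s * (1.0 - np.exp(-T_s / look_tau_s))


def simulate_fixation_trace(
    params: GeneratorParams,
    residence_s: float,
    rng: np.random.Generator,
    trial_key: tuple[str, int, int] = ("sim", 0, 1),
) -> FixationTrace:
    """Draw a per-ms Bernoulli looking indicator and run-length encode it.

    The indicator at millisecond ``m`` is 1 with probability
    ``look_p0 * exp(-(m/1000) / look_tau_s)``, independently across ms
    (the 1-ms resolution mirrors 1-kHz eye tracking); nothing is drawn
    beyond ``residence_s``.
    """
    if not 0.0 < residence_s <= 15.0:
        raise ValueError(f"residence_s must be in (0, 15], got {residence_s}")
    n_ms = s_to_ms(residence_s)
    p = looking_probability(np.arange(n_ms) / 1000.0, params.look_p0, params.look_tau_s)
    looking = rng.random(n_ms) < p
    return FixationTrace(trial_key=trial_key, intervals=_runs_to_intervals(looking))


def _runs_to_intervals(looking: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Convert a boolean per-ms indicator into half-open [start, end) runs."""
    if not looking.any():
        return ()
    padded = np.concatenate(([False], looking, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return tuple((int(s), int(e)) for s, e in zip(starts, ends))


def mvt_optimal_residence(
    gain_T_s: np.ndarray, gain_g: np.ndarray, travel_time_s: float
) -> float:
    """argmax over the gain grid of g(T) / (travel + T), smallest T on ties."""
    rates = np.asarray(gain_g, dtype=float) / (travel_time_s + np.asarray(gain_T_s, dtype=float))
    return float(np.asarray(gain_T_s)[int(np.argmax(rates))])


def _value_profile_analytic(bin_starts_s: np.ndarray, look_tau_s: float) -> np.ndarray:
    """Normalized per-bin looking value r(t) implied by the looking decay (max 1)."""
    if math.isinf(look_tau_s):
        return np.ones_like(bin_starts_s)
    r = np.exp(-bin_starts_s / look_tau_s)
    return r / r[0] if len(r) else r


def draw_residence_time(
    policy: PolicySpec,
    travel_time_s: float,
    rng: np.random.Generator,
    gain: "tuple[np.ndarray, np.ndarray] | None" = None,
    config: TaskConfig | None = None,
) -> tuple[float, bool]:
    """Draw one patch-residence time under ``policy``.

    Returns ``(residence_s, left_by_choice)``; ``left_by_choice`` is False
    when a stochastic policy never fires within the viewing window, in which
    case residence equals the full window (a timeout trial).

    ``gain`` is required for ``mvt_threshold`` and is a ``(T_grid_s, g)``
    pair of arrays.
    """
    if travel_time_s <= 0:
        raise ValueError("travel_time_s must be > 0")
    config = config or TaskConfig()
    window = config.viewing_window_s

    if policy.name == "juice_max":
        return (config.min_leave_fixation_ms + config.saccade_offset_ms) / 1000.0, True

    if policy.name == "mvt_threshold":
        if gain is None:
            raise ValueError("mvt_threshold policy requires a gain curve")
        t_star = mvt_optimal_residence(gain[0], gain[1], travel_time_s)
        sd = policy.parameters["noise_sd_s"]
        residence = t_star
        if sd > 0:
            for _ in range(100):  # truncate noise to (0, window]
                residence = t_star + rng.normal(0.0, sd)
                if 0.0 < residence <= window:
                    break
            else:
                residence = min(max(residence, 1e-3), window)
        return float(residence), True

    bin_w = config.bin_width_s
    n_bins = int(round(window / bin_w))
    starts = np.arange(n_bins) * bin_w
    centers = starts + bin_w / 2.0
    if policy.name == "hazard":
        b0, b1, b2, b3 = policy.parameters["coeffs"]
        r = _value_profile_analytic(starts, policy.parameters["look_tau_s"])
        hazard = b0 + b1 * r + b2 * centers + b3 * centers**2
    elif policy.name == "hyperbolic":
        r = _value_profile_analytic(starts, policy.parameters["look_tau_s"])
        hazard = r / (1.0 + policy.parameters["discount_k"] * travel_time_s)
    else:  # pragma: no cover - PolicySpec already validated the name
        raise ValueError(f"unknown policy {policy.name!r}")
    hazard = np.clip(hazard, 0.0, 1.0)
    fired = rng.random(n_bins) < hazard
    if not fired.any():
        return window, False
    i = int(np.argmax(fired))
    return float(starts[i] + rng.uniform(0.0, bin_w)), True


def simulate_sessions(
    params: GeneratorParams, config: TaskConfig | None = None
) -> tuple[list[TrialRecord], list[FixationTrace]]:
    """Generate full sessions: trials and their fixation traces.

    Each environment holds four type-A and four type-B patches; patches are
    chosen sequentially, picking a remaining A with probability
    ``preference_prob_A`` while both types remain. Travel time is drawn
    uniformly from the configured set per visit. The environment ends when
    its time budget (handling + residence + travel accumulated) is exhausted
    or all eight patches were visited. Identical ``(params, config)`` always
    produce identical tables.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(params.seed)
    travel_choices = np.asarray(config.travel_times_s, dtype=float)

    gain = None
    if params.policy == "mvt_threshold":
        grid = np.arange(config.n_bins) * config.bin_width_s + config.bin_width_s / 2.0
        gain = (grid, analytic_gain(grid, params.look_p0, params.look_tau_s))
    policy = params.policy_spec()

    trials: list[TrialRecord] = []
    fixations: list[FixationTrace] = []
    n_per_type = config.n_patches_per_type
    for env_index in range(params.n_environments):
        session_id = f"sess{env_index // params.environments_per_session:03d}"
        remaining = {"A": n_per_type, "B": n_per_type}
        elapsed = 0.0
        choice_index = 0
        while (remaining["A"] or remaining["B"]) and elapsed < config.environment_timeout_s:
            choice_index += 1
            if remaining["A"] and remaining["B"]:
                patch_type = "A" if rng.random() < params.preference_prob_A else "B"
            else:
                patch_type = "A" if remaining["A"] else "B"
            remaining[patch_type] -= 1
            travel = float(rng.choice(travel_choices))
            residence, left = draw_residence_time(policy, travel, rng, gain=gain, config=config)
            trial = TrialRecord(
                session_id=session_id,
                subject_id=params.subject_id,
                environment_type=params.environment_type,
                environment_index=env_index,
                choice_index=choice_index,
                patch_type=patch_type,
                travel_time_s=travel,
                residence_time_s=residence,
                left_by_choice=left,
            )
            trials.append(trial)
            fixations.append(
                simulate_fixation_trace(params, residence, rng, trial_key=trial.key)
            )
            elapsed += config.handling_time_s + residence + travel
    return trials, fixations
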