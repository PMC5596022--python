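import numpy as np
import pytest

from patchforage import (
    FixationTrace,
    GeneratorParams,
    TaskConfig,
    TrialRecord,
    simulate_sessions,
)


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def sim_dataset(config):
    """A default (hazard-policy) synthetic dataset, ~800 visits."""
    params = GeneratorParams(n_environments=100, seed=7)
    return simulate_sessions(params, config)


@pytest.fixture(scope="session")
def mvt_dataset(config):
    """Sessions generated by an agent following the marginal-value rule."""
    params = GeneratorParams(n_environments=125, policy="mvt_threshold", seed=11)
    return simulate_sessions(params, config)


def make_trial(
    session_id="s1",
    environment_index=0,
    choice_index=1,
    patch_type="A",
    travel_time_s=1.0,
    residence_time_s=2.0,
    left_by_choice=True,
    environment_type="color_valence",
    subject_id="m1",
):
    return TrialRecord(
        session_id=session_id,
        subject_id=subject_id,
        environment_type=environment_type,
        environment_index=environment_index,
        choice_index=choice_index,
        patch_type=patch_type,
        travel_time_s=travel_time_s,
        residence_time_s=residence_time_s,
        left_by_choice=left_by_choice,
    )


def make_environment(order, environment_index=0, session_id="s1", **kw):
    """Eight trials whose patch types follow ``order`` (string of A/B)."""
    return [
        make_trial(
            session_id=session_id,
            environment_index=environment_index,
            choice_index=i + 1,
            patch_type=pt,
            **kw,
        )
        for i, pt in enumerate(order)
    ]


@pytest.fixture
def tiny_trials():
    """Two complete environments: all-A-first, then alternating."""
    return make_environment("AAAABBBB", 0) + make_environment("ABABABAB", 1)


def trace_for(trial, intervals):
    return FixationTrace(trial_key=trial.key, intervals=tuple(intervals))
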