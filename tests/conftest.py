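import numpy as np
import pytest

from pericalc.epochs import build_rate_table, build_trials
from pericalc.session_io import ClockMap
from pericalc.synth import CohortSpec, TuningProfile, generate_session
from pericalc.task import TaskSpec


@pytest.fixture(scope="session")
def fast_cue_task() -> TaskSpec:
    """Cue-guided task with the short-ITI test profile."""
    return TaskSpec(task_kind="cue_guided", iti_mean=10.0,
                    session_length=600.0)


@pytest.fixture(scope="session")
def fast_delay_task() -> TaskSpec:
    return TaskSpec(task_kind="delay", iti_mean=10.0, session_length=600.0)


@pytest.fixture(scope="session")
def all_correct_cohort() -> CohortSpec:
    return CohortSpec(group_label="g", trial_outcome_mixture=(1.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def untuned_session(fast_cue_task, all_correct_cohort):
    """A small all-correct session of untuned cells, parsed and rated."""
    profiles = [TuningProfile(cell_id=f"c{i}", baseline_rate=1.0)
                for i in range(20)]
    rec, log, truth, _ = generate_session(fast_cue_task, profiles,
                                          all_correct_cohort, seed=11)
    trials = build_trials(log, fast_cue_task, ClockMap.identity())
    table = build_rate_table(rec, trials, fast_cue_task)
    return rec, log, truth, trials, table
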