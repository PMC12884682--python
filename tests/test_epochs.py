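"""Trial parsing, epoch window definitions and epoch-rate assembly."""

import numpy as np
import pandas as pd
import pytest

from pericalc.epochs import (EpochRateTable, Trial, build_rate_table,
                             build_trials, epoch_windows, event_rate,
                             frame_to_rate_table, rate_table_to_frame)
from pericalc.session_io import BehaviorLog, ClockMap, SessionRecording
from pericalc.task import TaskSpec


def _log(rows):
    return BehaviorLog(events=pd.DataFrame(
        rows, columns=["time_s", "event_code", "port"]))


CUE = TaskSpec(task_kind="cue_guided", iti_mean=10.0, session_length=200.0)
DELAY = TaskSpec(task_kind="delay", iti_mean=10.0, session_length=200.0)


def test_build_trials_outcomes_cue_task():
    rows = [
        (0.0, "iti_start", ""),
        # correct: cued left, left poke at +1.0 within the 1.5 s window
        (10.0, "trial_available", ""), (12.0, "initiation_poke", "center"),
        (12.0, "cue_on", "left"), (13.0, "side_poke_left", "left"),
        (13.0, "reward_delivery", "left"), (19.0, "iti_start", ""),
        # omitted: no side poke in the window
        (30.0, "trial_available", ""), (32.0, "initiation_poke", "center"),
        (32.0, "cue_on", "right"), (33.5, "iti_start", ""),
        # incorrect: poke to the non-cued side
        (45.0, "trial_available", ""), (47.0, "initiation_poke", "center"),
        (47.0, "cue_on", "right"), (47.8, "side_poke_left", "left"),
        (47.8, "iti_start", ""),
    ]
    trials = build_trials(_log(rows), CUE)
    assert list(trials["outcome"]) == ["correct", "omitted", "incorrect"]
    assert trials.loc[0, "reward_time"] == 13.0
    assert np.isnan(trials.loc[1, "response_time"])
    assert trials.loc[2, "response_port"] == "left"
    assert trials["premature_count"].tolist() == [0, 0, 0]
    # accounting: every initiation starts exactly one trial
    n_init = sum(1 for r in rows if r[1] == "initiation_poke")
    assert len(trials) == n_init


def test_build_trials_premature_in_delay_task():
    rows = [
        (0.0, "iti_start", ""),
        (10.0, "trial_available", ""), (12.0, "initiation_poke", "center"),
        (12.5, "side_poke_left", "left"), (14.0, "side_poke_right", "right"),
        (15.0, "cue_on", "left"), (15.8, "side_poke_left", "left"),
        (15.8, "reward_delivery", "left"),
    ]
    trials = build_trials(_log(rows), DELAY)
    assert trials.loc[0, "outcome"] == "correct"
    assert trials.loc[0, "premature_count"] == 2
    assert trials.loc[0, "reward_time"] == 15.8


def test_build_trials_first_trial_flagged_incomplete():
    rows = [
        (2.0, "trial_available", ""), (4.0, "initiation_poke", "center"),
        (4.0, "cue_on", "left"), (5.0, "side_poke_left", "left"),
        (5.0, "reward_delivery", "left"),
    ]
    trials = build_trials(_log(rows), CUE)
    assert len(trials) == 1
    assert not trials.loc[0, "baseline_complete"]


def test_build_trials_clock_conversion():
    rows = [(0.0, "iti_start", ""), (10.0, "trial_available", ""),
            (12.0, "initiation_poke", "center"), (12.0, "cue_on", "left"),
            (13.0, "side_poke_left", "left"),
            (13.0, "reward_delivery", "left")]
    cm = ClockMap(offset=2.0, drift=1.0)
    trials = build_trials(_log(rows), CUE, cm)
    assert trials.loc[0, "initiation_time"] == pytest.approx(14.0)


def test_epoch_windows_hand_trial():
    trial = Trial(index=0, availability_time=95.0, initiation_time=100.0,
                  cue_on_time=100.0, response_time=100.9,
                  response_port="left", cued_port="left", reward_time=100.9,
                  outcome="correct", premature_count=0,
                  preceding_iti=(50.0, 95.0))
    win = dict(epoch_windows(trial, CUE))
    assert win["T"] == (98.0, 100.0)
    assert win["C"] == (100.0, 100.9)
    assert win["R"] == (100.9, 103.9)
    assert win["P"] == (103.9, 106.9)
    assert win["baseline"] == (89.0, 95.0)
    # R/P never overlap; T precedes initiation; baseline precedes availability
    assert win["R"][1] == win["P"][0]
    assert win["T"][1] <= trial.initiation_time
    assert win["baseline"][1] <= trial.availability_time


def test_epoch_windows_delay_task():
    trial = Trial(index=0, availability_time=196.0, initiation_time=200.0,
                  cue_on_time=203.0, response_time=203.7,
                  response_port="left", cued_port="left", reward_time=203.7,
                  outcome="correct", premature_count=1,
                  preceding_iti=(180.0, 196.0))
    win = dict(epoch_windows(trial, DELAY))
    assert win["D"] == (200.0, 203.0)
    assert win["C"] == (203.0, 203.7)
    assert set(win) == {"T", "C", "D", "R", "P", "baseline"}


def test_epoch_windows_strict_contract():
    bad = Trial(index=0, availability_time=0.0, initiation_time=2.0,
                cue_on_time=2.0, response_time=None, response_port="",
                cued_port="left", reward_time=None, outcome="omitted",
                premature_count=0, preceding_iti=(-10.0, 0.0))
    with pytest.raises(ValueError, match="correct trials"):
        epoch_windows(bad, CUE)
    bad2 = Trial(index=0, availability_time=0.0, initiation_time=2.0,
                 cue_on_time=2.0, response_time=3.0, response_port="left",
                 cued_port="left", reward_time=None, outcome="correct",
                 premature_count=0, preceding_iti=(-10.0, 0.0))
    with pytest.raises(ValueError, match="consistency"):
        epoch_windows(bad2, CUE)


def test_event_rate_counting():
    trace = np.zeros(100)
    trace[[3, 10, 11, 40, 41, 59]] = 1.0
    assert event_rate(trace, (0, 60)) == pytest.approx(2.0)  # 6 in 3 s
    assert event_rate(np.zeros(100), (0, 60)) == 0.0
    with pytest.raises(ValueError):
        event_rate(trace, (10, 10))
    # brute-force frame scan oracle on a random sparse trace
    rng = np.random.default_rng(2)
    sparse = rng.random(200) * (rng.random(200) < 0.1)
    got = event_rate(sparse, (20, 140), threshold=0.0)
    brute = sum(1 for v in sparse[20:140] if v > 0) / 6.0
    assert got == pytest.approx(brute)


def test_event_rate_scale_equivariance():
    """Doubling the window at the same per-second event density leaves
    the rate unchanged."""
    trace = np.tile([1.0, 0, 0, 0], 100)  # 5 events/s everywhere
    assert event_rate(trace, (0, 40)) == event_rate(trace, (0, 80))


def _tiny_recording_and_trials():
    """2 cells, 3 hand-placed correct trials on a shared 20 Hz grid."""
    n_frames = 20 * 200
    traces = np.zeros((2, n_frames))
    traces[0, ::10] = 1.0   # 2 events/s
    traces[1, ::40] = 0.5   # 0.5 events/s
    rec = SessionRecording(cell_ids=["a", "b"], traces=traces,
                           frame_times=np.arange(n_frames) / 20.0)
    rows = []
    for k, t0 in enumerate((20.0, 80.0, 140.0)):
        rows.append({
            "trial": k, "availability_time": t0, "initiation_time": t0 + 2,
            "cue_on_time": t0 + 2, "response_time": t0 + 3,
            "response_port": "left", "cued_port": "left",
            "reward_time": t0 + 3, "outcome": "correct",
            "premature_count": 0, "iti_start": t0 - 15, "iti_end": t0,
            "baseline_complete": True,
        })
    return rec, pd.DataFrame(rows)


def test_build_rate_table_shape_and_serialization():
    rec, trials = _tiny_recording_and_trials()
    table = build_rate_table(rec, trials, CUE)
    assert table.rates.shape == (2, 3, 4)
    assert table.baseline_rates.shape == (2, 3)
    # deterministic traces: rates equal the known densities everywhere
    assert np.allclose(table.baseline_rates[0], 2.0)
    assert np.allclose(table.baseline_rates[1], 0.5)
    round_trip = frame_to_rate_table(rate_table_to_frame(table))
    assert np.allclose(round_trip.rates, table.rates)
    assert np.allclose(round_trip.baseline_rates, table.baseline_rates)
    assert round_trip.epoch_labels == table.epoch_labels


def test_build_rate_table_excludes_incomplete_baseline():
    rec, trials = _tiny_recording_and_trials()
    trials.loc[0, "baseline_complete"] = False
    table = build_rate_table(rec, trials, CUE)
    assert table.n_trials == 2
    assert table.n_trials_excluded == 1
    assert 0 not in table.trial_indices


def test_build_rate_table_requires_usable_trials():
    rec, trials = _tiny_recording_and_trials()
    trials["outcome"] = "omitted"
    with pytest.raises(ValueError, match="no usable"):
        build_rate_table(rec, trials, CUE)


def test_untuned_epoch_rates_match_baseline(untuned_session):
    """Monte-Carlo sanity: per-epoch mean rates of untuned cells equal the
    baseline mean within 3 SEs of the epoch-mean estimate."""
    *_, table = untuned_session
    base_mean = table.baseline_rates.mean()
    for k in range(len(table.epoch_labels)):
        vals = table.rates[:, :, k].ravel()
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - base_mean) < 3 * se + 0.05


def test_trial_accounting(untuned_session):
    _, _, truth, trials, _ = untuned_session
    counts = trials["outcome"].value_counts()
    assert counts.sum() == len(trials)
    assert set(counts.index) <= {"correct", "incorrect", "omitted"}
    # parsed trials agree with the generator's ground truth
    assert list(trials["outcome"]) == list(truth["outcome"])
    np.testing.assert_allclose(trials["initiation_time"],
                               truth["initiation_time"], atol=1e-9)
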