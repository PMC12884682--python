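"""Trial categorization, epoch windows and per-trial epoch event rates.

Trials are parsed from the behavioral event stream and categorized as
*correct* (a response to the cued port within the response window, always
rewarded), *incorrect* (a response to the non-cued port) or *omitted* (no
response).  In the delay task, side pokes during the enforced delay are
premature responses: counted, never outcome-changing.

For each correct trial, event rates are computed in the task's named
epochs (see :mod:`pericalc.task`) and paired with a baseline rate from the
last 6 s of the immediately preceding ITI.  The classification stage
(:mod:`pericalc.classify`) consumes the resulting
:class:`EpochRateTable`.

Event-rate definition: the deconvolved trace is reduced to events by
thresholding — the rate in a window is the number of frames whose
amplitude exceeds ``threshold`` (default 0) divided by the window
duration.  An amplitude-weighted variant (summed supra-threshold
amplitude per second) is available via ``weighted=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pericalc.session_io import BehaviorLog, ClockMap, SessionRecording
from pericalc.task import TaskSpec

logger = logging.getLogger(__name__)

#: Length of the trial-initiation (T) epoch, seconds before the poke.
T_EPOCH_DURATION = 2.0

TRIAL_COLUMNS = [
    "trial", "availability_time", "initiation_time", "cue_on_time",
    "response_time", "response_port", "cued_port", "reward_time",
    "outcome", "premature_count", "iti_start", "iti_end",
    "baseline_complete",
]


@dataclass
class Trial:
    """One parsed trial; all times in seconds on a single clock."""

    index: int
    availability_time: float
    initiation_time: float
    cue_on_time: float
    response_time: float | None
    response_port: str
    cued_port: str
    reward_time: float | None
    outcome: str
    premature_count: int
    preceding_iti: tuple[float, float]
    baseline_complete: bool = True


def trials_to_frame(trials: list[Trial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append({
            "trial": t.index,
            "availability_time": t.availability_time,
            "initiation_time": t.initiation_time,
            "cue_on_time": t.cue_on_time,
            "response_time": np.nan if t.response_time is None else t.response_time,
            "response_port": t.response_port,
            "cued_port": t.cued_port,
            "reward_time": np.nan if t.reward_time is None else t.reward_time,
            "outcome": t.outcome,
            "premature_count": t.premature_count,
            "iti_start": t.preceding_iti[0],
            "iti_end": t.preceding_iti[1],
            "baseline_complete": t.baseline_complete,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def build_trials(log: BehaviorLog, task: TaskSpec,
                 clock: ClockMap | None = None) -> pd.DataFrame:
    """Parse the behavioral event stream into a trial table.

    Every initiation poke starts exactly one trial.  Outcomes follow the
    task rules above; side pokes between initiation and cue onset in the
    delay task increment ``premature_count`` only.  When ``clock`` is
    given, all times in the returned table are converted to the imaging
    clock; otherwise they remain on the behavioral clock.

    A first trial with no (or a too-short) preceding ITI is retained but
    flagged ``baseline_complete = False``.
    """
    trials: list[Trial] = []
    last_iti_start: float | None = None
    availability: float | None = None
    iti_span: tuple[float, float] | None = None
    cur: Trial | None = None

    def close(trial: Trial | None) -> None:
        if trial is None:
            return
        if trial.response_time is None:
            trial.outcome = "omitted"
        elif trial.response_port == trial.cued_port:
            trial.outcome = "correct"
        else:
            trial.outcome = "incorrect"
        if trial.outcome == "correct" and trial.reward_time is None:
            # Generator and rig always reward correct responses at the poke.
            trial.reward_time = trial.response_time
        trials.append(trial)

    for row in log.events.itertuples(index=False):
        t, code, port = float(row.time_s), row.event_code, str(row.port)
        if code == "iti_start":
            last_iti_start = t
        elif code == "trial_available":
            close(cur)
            cur = None
            availability = t
            start = last_iti_start if last_iti_start is not None else np.nan
            iti_span = (start, t)
        elif code == "initiation_poke":
            if availability is None:
                availability = t
                iti_span = (np.nan, t)
            complete = (iti_span is not None
                        and np.isfinite(iti_span[0])
                        and iti_span[1] - iti_span[0] >= task.baseline_duration)
            cue_on = t if task.task_kind == "cue_guided" else t + task.delay_duration
            cur = Trial(index=len(trials), availability_time=availability,
                        initiation_time=t, cue_on_time=cue_on,
                        response_time=None, response_port="",
                        cued_port="", reward_time=None, outcome="omitted",
                        premature_count=0, preceding_iti=iti_span,
                        baseline_complete=bool(complete))
        elif code == "cue_on" and cur is not None:
            cur.cue_on_time = t
            cur.cued_port = port
        elif code in ("side_poke_left", "side_poke_right") and cur is not None:
            if t < cur.cue_on_time:
                cur.premature_count += 1
            elif (cur.response_time is None
                  and t < cur.cue_on_time + task.cue_duration):
                cur.response_time = t
                cur.response_port = port
        elif code == "reward_delivery" and cur is not None:
            cur.reward_time = t
    close(cur)

    frame = trials_to_frame(trials)
    if clock is not None:
        for col in ("availability_time", "initiation_time", "cue_on_time",
                    "response_time", "reward_time", "iti_start", "iti_end"):
            frame[col] = clock.to_imaging(frame[col].to_numpy())
    return frame


def epoch_windows(trial, task: TaskSpec, *, strict: bool = True):
    """Absolute half-open epoch windows for one trial.

    ``trial`` is any object with trial-table attributes (a
    :class:`Trial`, or a row from ``DataFrame.itertuples``).  Returns
    ``[(label, (start, end)), ...]`` in canonical epoch order with the
    ``"baseline"`` window (last 6 s of the preceding ITI) appended.

    With ``strict=True`` (the classification contract) the trial must be
    correct and carry a reward time.  With ``strict=False`` only the
    windows that exist given the trial's outcome are returned (used by
    the synthetic generator to place tuning on every initiated trial).
    """
    outcome = trial.outcome
    reward = getattr(trial, "reward_time", None)
    reward = None if reward is None or not np.isfinite(reward) else float(reward)
    response = getattr(trial, "response_time", None)
    response = None if response is None or not np.isfinite(response) else float(response)
    if strict:
        if outcome != "correct":
            raise ValueError("epoch windows are defined on correct trials only")
        if reward is None:
            raise ValueError("correct trial without a reward time "
                             "(internal consistency error)")

    init = float(trial.initiation_time)
    cue_on = float(trial.cue_on_time)
    windows: dict[str, tuple[float, float]] = {}
    windows["T"] = (init - T_EPOCH_DURATION, init)
    if task.task_kind == "delay":
        windows["D"] = (init, init + task.delay_duration)
    if response is not None:
        c_start = init if task.task_kind == "cue_guided" else cue_on
        if response > c_start:
            windows["C"] = (c_start, response)
    if reward is not None:
        windows["R"] = (reward, reward + task.reward_epoch)
        lo, hi = task.post_reward_epoch
        windows["P"] = (reward + lo, reward + hi)

    out = [(lab, windows[lab]) for lab in task.epoch_labels if lab in windows]
    iti_end = float(trial.iti_end if hasattr(trial, "iti_end")
                    else trial.preceding_iti[1])
    out.append(("baseline", (iti_end - task.baseline_duration, iti_end)))
    return out


def event_rate(trace: np.ndarray, window: tuple[int, int],
               threshold: float = 0.0, frame_rate: float = 20.0,
               weighted: bool = False) -> float:
    """Event rate of one cell in a half-open frame window, events/second.

    Counts frames whose amplitude strictly exceeds ``threshold`` and
    divides by the window duration.  ``weighted=True`` sums the
    supra-threshold amplitudes instead of counting frames.
    """
    start, end = window
    if end <= start:
        raise ValueError("empty epoch window")
    seg = np.asarray(trace[start:end])
    dur = (end - start) / frame_rate
    if weighted:
        return float(seg[seg > threshold].sum() / dur)
    return float(np.count_nonzero(seg > threshold) / dur)


@dataclass
class EpochRateTable:
    """Cells × correct-trials × epochs event rates with paired baselines."""

    rates: np.ndarray            # (n_cells, n_trials, n_epochs)
    baseline_rates: np.ndarray   # (n_cells, n_trials)
    epoch_labels: list[str]
    trial_indices: np.ndarray
    cell_ids: list[str]
    n_trials_excluded: int = 0

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]

    def baselines(self, pairing: str = "per_trial") -> np.ndarray:
        """Per-trial baseline matrix under the chosen pairing mode.

        ``"per_trial"`` pairs each trial with its own preceding-ITI rate;
        ``"session_mean"`` pairs every trial with the cell's across-ITI
        average baseline.
        """
        if pairing == "per_trial":
            return self.baseline_rates
        if pairing == "session_mean":
            mean = self.baseline_rates.mean(axis=1, keepdims=True)
            return np.broadcast_to(mean, self.baseline_rates.shape)
        raise ValueError(f"unknown pairing mode: {pairing!r}")


def rate_table_to_frame(table: EpochRateTable) -> pd.DataFrame:
    """Serialize an :class:`EpochRateTable` to a long-format table
    (columns: cell_id, trial, epoch, rate, baseline_rate)."""
    n_cells, n_trials, n_epochs = table.rates.shape
    cells = np.repeat(table.cell_ids, n_trials * n_epochs)
    tr = np.tile(np.repeat(table.trial_indices, n_epochs), n_cells)
    ep = np.tile(table.epoch_labels, n_cells * n_trials)
    base = np.repeat(table.baseline_rates.ravel(), n_epochs)
    return pd.DataFrame({"cell_id": cells, "trial": tr, "epoch": ep,
                         "rate": table.rates.ravel(),
                         "baseline_rate": base})


def frame_to_rate_table(df: pd.DataFrame) -> EpochRateTable:
    """Inverse of :func:`rate_table_to_frame`."""
    cell_ids = list(dict.fromkeys(df["cell_id"].astype(str)))
    trial_idx = np.array(sorted(df["trial"].unique()))
    labels = list(dict.fromkeys(df["epoch"]))
    piv = df.set_index(["cell_id", "trial", "epoch"])
    rates = (piv["rate"].unstack(["trial", "epoch"])
             .reindex(index=cell_ids)
             .reindex(columns=pd.MultiIndex.from_product([trial_idx, labels]))
             .to_numpy().reshape(len(cell_ids), len(trial_idx), len(labels)))
    base = (df.drop_duplicates(["cell_id", "trial"])
            .pivot(index="cell_id", columns="trial", values="baseline_rate")
            .reindex(index=cell_ids, columns=trial_idx).to_numpy())
    return EpochRateTable(rates=rates, baseline_rates=base,
                          epoch_labels=labels, trial_indices=trial_idx,
                          cell_ids=cell_ids)


def _to_frame_span(window: tuple[float, float], t0: float,
                   frame_rate: float, n_frames: int):
    s = int(np.floor((window[0] - t0) * frame_rate + 1e-9))
    e = int(np.floor((window[1] - t0) * frame_rate + 1e-9))
    if s < 0 or e > n_frames or e <= s:
        return None
    return s, e


def build_rate_table(recording: SessionRecording, trials: pd.DataFrame,
                     task: TaskSpec, *, threshold: float = 0.0,
                     weighted: bool = False) -> EpochRateTable:
    """Assemble the epoch-rate table the permutation test consumes.

    Uses correct trials with a complete preceding-ITI baseline whose
    epoch windows fall entirely inside the recording; excluded trials are
    counted (``n_trials_excluded``) and logged.  Trial times must be on
    the imaging clock (see :func:`build_trials`).
    """
    labels = task.epoch_labels
    t0 = float(recording.frame_times[0])
    fr = recording.frame_rate
    usable: list[tuple[int, list[tuple[int, int]], tuple[int, int]]] = []
    n_candidates = 0
    for row in trials.itertuples(index=False):
        if row.outcome != "correct":
            continue
        n_candidates += 1
        if not row.baseline_complete:
            continue
        spans = {}
        ok = True
        for lab, win in epoch_windows(row, task):
            span = _to_frame_span(win, t0, fr, recording.n_frames)
            if span is None:
                ok = False
                break
            spans[lab] = span
        if not ok or any(lab not in spans for lab in labels):
            continue
        usable.append((int(row.trial), [spans[lab] for lab in labels],
                       spans["baseline"]))
    n_excluded = n_candidates - len(usable)
    if n_excluded:
        logger.info("build_rate_table: excluded %d correct trial(s) with "
                    "incomplete baseline or out-of-recording windows",
                    n_excluded)
    if not usable:
        raise ValueError("no usable correct trials with a complete baseline")

    n_cells = recording.n_cells
    n_trials = len(usable)
    rates = np.empty((n_cells, n_trials, len(labels)))
    base = np.empty((n_cells, n_trials))
    tr = recording.traces

    def window_rates(span):
        s, e = span
        dur = (e - s) / fr
        seg = tr[:, s:e]
        if weighted:
            return np.where(seg > threshold, seg, 0.0).sum(axis=1) / dur
        return np.count_nonzero(seg > threshold, axis=1) / dur

    for j, (_, spans, bspan) in enumerate(usable):
        for k, span in enumerate(spans):
            rates[:, j, k] = window_rates(span)
        base[:, j] = window_rates(bspan)

    return EpochRateTable(
        rates=rates, baseline_rates=base, epoch_labels=list(labels),
        trial_indices=np.array([u[0] for u in usable]),
        cell_ids=list(recording.cell_ids), n_trials_excluded=n_excluded)
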