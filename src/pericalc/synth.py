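"""Synthetic operant imaging sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes,
end to end: self-initiated trials with a variable ITI, an outcome mixture
(correct / incorrect / omitted), per-frame Poisson event trains whose
rate is multiplicatively modulated in named trial epochs, gamma-distributed
event amplitudes, 5 s on/off sync pulses seen on both clocks through a
configurable affine clock model (offset + drift + per-edge jitter), and —
for the locomotion stage — grayscale frame stacks with a moving blob.

Event model: within a 50 ms frame the event count is Poisson with mean
``baseline_rate × multiplier(epoch) / frame_rate``; a frame holding ``k``
events carries the sum of ``k`` independent Gamma(2, amplitude_scale/2)
amplitudes (mean ``k × amplitude_scale``).  Rate multipliers apply only
within the epoch windows of each initiated trial; ITIs always run at the
baseline rate, so per-trial baseline windows are uncontaminated ground
truth.

Scheduling keeps the fast-test profile (short ITIs) semantically
identical to field conditions: the ITI timer starts only after the 6 s
post-reward period of a correct trial, and the initiation latency is
drawn U(2, 4) s after availability, so neither the tuned post-reward
epochs nor the T window can ever overlap a baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pericalc.epochs import Trial, epoch_windows, trials_to_frame
from pericalc.session_io import BehaviorLog, ClockMap, SessionRecording
from pericalc.task import FRAME_RATE, TaskSpec, parse_category

SYNC_HALF_PERIOD = 5.0  # 5 s on / 5 s off pulse train

#: Default trial-outcome mixture (correct, incorrect, omitted).
DEFAULT_OUTCOME_MIXTURE = (0.59, 0.05, 0.36)


@dataclass(frozen=True)
class TuningProfile:
    """Ground-truth tuning of one synthetic cell.

    ``epoch_multipliers`` maps epoch letters to multiplicative rate
    factors (1.0 = untuned, 0.0 = silenced in that epoch); multipliers
    for epochs absent from the task are ignored.
    """

    cell_id: str
    baseline_rate: float = 1.0
    epoch_multipliers: dict[str, float] = field(default_factory=dict)
    amplitude_scale: float = 1.0
    category: str = ""

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be > 0")
        if any(m < 0 for m in self.epoch_multipliers.values()):
            raise ValueError("epoch multipliers must be >= 0")

    @classmethod
    def from_category(cls, cell_id: str, category: str, *,
                      baseline_rate: float = 1.0,
                      excited_multiplier: float = 5.0,
                      inhibited_multiplier: float = 0.1,
                      amplitude_scale: float = 1.0) -> "TuningProfile":
        """Build a profile from a category string such as ``"R+P-"``."""
        mult = {e: (excited_multiplier if s == "+" else inhibited_multiplier)
                for e, s in parse_category(category)}
        return cls(cell_id=cell_id, baseline_rate=baseline_rate,
                   epoch_multipliers=mult, amplitude_scale=amplitude_scale,
                   category=category)


@dataclass(frozen=True)
class CohortSpec:
    """One group of synthetic mice sharing behavioral statistics.

    ``category_mixture`` maps category strings (``""`` = untuned) to
    proportions summing to 1; each cell's category is drawn from it.
    ``trial_outcome_mixture`` is (correct, incorrect, omitted).
    ``response_latency`` is the (mean, sd) of the cue→response latency,
    normal truncated to the response window.  ``premature_rate`` is the
    rate (pokes/s) of the homogeneous Poisson premature-poke process
    during the delay.  The clock fields set the affine behavioral→imaging
    clock model of each generated session.
    """

    group_label: str
    n_mice: int = 1
    cells_per_mouse: int = 50
    category_mixture: dict[str, float] = field(
        default_factory=lambda: {"": 1.0})
    trial_outcome_mixture: tuple[float, float, float] = DEFAULT_OUTCOME_MIXTURE
    response_latency: tuple[float, float] = (0.93, 0.3)
    premature_rate: float = 0.1
    baseline_rate: float = 1.0
    excited_multiplier: float = 5.0
    inhibited_multiplier: float = 0.1
    amplitude_scale: float = 1.0
    clock_offset: float = 0.0
    clock_drift: float = 1.0
    sync_jitter_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1 or self.cells_per_mouse < 1:
            raise ValueError("n_mice and cells_per_mouse must be >= 1")
        if abs(sum(self.category_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("category_mixture proportions must sum to 1")
        if abs(sum(self.trial_outcome_mixture) - 1.0) > 1e-9:
            raise ValueError("trial_outcome_mixture must sum to 1")
        for cat in self.category_mixture:
            parse_category(cat)  # raises on malformed keys


@dataclass
class SessionBundle:
    """One generated session plus its ground truth."""

    group_label: str
    mouse_index: int
    recording: SessionRecording
    log: BehaviorLog
    trials: pd.DataFrame
    profiles: list[TuningProfile]


def _draw_latency(rng: np.random.Generator, mean: float, sd: float,
                  window: float) -> float:
    lo, hi = 0.05, max(0.06, window - 1e-3)
    for _ in range(100):
        lat = rng.normal(mean, sd)
        if lo < lat < hi:
            return float(lat)
    return float(np.clip(mean, lo, hi))


def _schedule_trials(task: TaskSpec, cohort: CohortSpec,
                     rng: np.random.Generator) -> list[Trial]:
    lo, hi = task.iti_bounds
    margin = task.max_trial_span + 2.0
    outcomes = np.array(["correct", "incorrect", "omitted"])
    p_outcome = np.asarray(cohort.trial_outcome_mixture, dtype=float)
    trials: list[Trial] = []
    t = 0.0  # behavioral clock; current iti_start
    while True:
        iti = rng.uniform(lo, hi)
        avail = t + iti
        if avail + margin > task.session_length:
            break
        init = avail + rng.uniform(*task.init_latency)
        outcome = str(rng.choice(outcomes, p=p_outcome))
        cued = str(rng.choice(["left", "right"]))
        premature: list[tuple[float, str]] = []
        if task.task_kind == "delay":
            cue_on = init + task.delay_duration
            k = rng.poisson(cohort.premature_rate * task.delay_duration)
            for pt in np.sort(rng.uniform(init, cue_on, size=k)):
                premature.append((float(pt), str(rng.choice(["left", "right"]))))
        else:
            cue_on = init

        response = reward = None
        port = ""
        if outcome != "omitted":
            lat = _draw_latency(rng, *cohort.response_latency,
                                task.cue_duration)
            response = cue_on + lat
            if outcome == "correct":
                port = cued
                reward = response
            else:
                port = "left" if cued == "right" else "right"

        if reward is not None:
            trial_end = reward + task.post_reward_epoch[1]
        elif response is not None:
            trial_end = response
        else:
            trial_end = cue_on + task.cue_duration

        trial = Trial(index=len(trials), availability_time=avail,
                      initiation_time=init, cue_on_time=cue_on,
                      response_time=response, response_port=port,
                      cued_port=cued, reward_time=reward, outcome=outcome,
                      premature_count=len(premature),
                      preceding_iti=(t, avail),
                      baseline_complete=(avail - t) >= task.baseline_duration)
        trial.premature_times = premature  # type: ignore[attr-defined]
        trials.append(trial)
        t = trial_end
    return trials


def _events_frame(trials: list[Trial]) -> pd.DataFrame:
    rows: list[tuple[float, str, str]] = [(0.0, "iti_start", "")]
    for tr in trials:
        rows.append((tr.availability_time, "trial_available", ""))
        rows.append((tr.initiation_time, "initiation_poke", "center"))
        for pt, pport in getattr(tr, "premature_times", []):
            rows.append((pt, f"side_poke_{pport}", pport))
        rows.append((tr.cue_on_time, "cue_on", tr.cued_port))
        if tr.response_time is not None:
            rows.append((tr.response_time, f"side_poke_{tr.response_port}",
                         tr.response_port))
        if tr.reward_time is not None:
            rows.append((tr.reward_time, "reward_delivery", tr.response_port))
        if tr.reward_time is not None:
            end = tr.reward_time + 6.0
        elif tr.response_time is not None:
            end = tr.response_time
        else:
            end = tr.cue_on_time
        rows.append((end, "iti_start", ""))
    rows.sort(key=lambda r: r[0])
    return pd.DataFrame(rows, columns=["time_s", "event_code", "port"])


def generate_session(task: TaskSpec, profiles: list[TuningProfile],
                     cohort: CohortSpec | None = None, seed=0,
                     ) -> tuple[SessionRecording, BehaviorLog,
                                pd.DataFrame, list[TuningProfile]]:
    """Generate one complete synthetic session.

    Returns ``(recording, log, ground-truth trial table, profiles)``.
    Behavior (events, sync edges) lives on the behavioral clock; the
    trace matrix lives on the imaging clock, related by the cohort's
    affine clock model.  Regeneration with the same arguments is
    bit-identical.
    """
    if not profiles:
        raise ValueError("at least one tuning profile (cell) is required")
    if cohort is None:
        cohort = CohortSpec(group_label="default")
    rng = np.random.default_rng(seed)

    trials = _schedule_trials(task, cohort, rng)
    if not trials:
        raise ValueError(
            "session too short for one full trial plus ITI; increase "
            "session_length or reduce iti_mean")

    n_frames = int(round(task.session_length * FRAME_RATE))
    frame_times = np.arange(n_frames) / FRAME_RATE
    true_clock = ClockMap(offset=cohort.clock_offset,
                          drift=cohort.clock_drift)

    # Epoch frame masks on the imaging clock, per epoch label.
    epoch_frames: dict[str, list[tuple[int, int]]] = {}
    for tr in trials:
        for lab, (s, e) in epoch_windows(tr, task, strict=False):
            if lab == "baseline":
                continue
            si, ei = true_clock.to_imaging([s, e])
            fs = max(0, int(np.floor(si * FRAME_RATE + 1e-9)))
            fe = min(n_frames, int(np.floor(ei * FRAME_RATE + 1e-9)))
            if fe > fs:
                epoch_frames.setdefault(lab, []).append((fs, fe))

    traces = np.zeros((len(profiles), n_frames))
    lam = np.empty(n_frames)
    for i, prof in enumerate(profiles):
        lam.fill(prof.baseline_rate / FRAME_RATE)
        for lab, mult in prof.epoch_multipliers.items():
            if mult == 1.0:
                continue
            for fs, fe in epoch_frames.get(lab, []):
                lam[fs:fe] *= mult
        counts = rng.poisson(lam)
        nz = np.flatnonzero(counts)
        if nz.size:
            k = counts[nz].astype(float)
            traces[i, nz] = rng.gamma(2.0 * k, prof.amplitude_scale / 2.0)

    # Sync pulse edges every 5 s on the behavioral clock, observed on the
    # imaging clock through the affine model plus optional jitter.
    beh_edges = np.arange(0.0, task.session_length, SYNC_HALF_PERIOD)
    img_edges = true_clock.to_imaging(beh_edges)
    if cohort.sync_jitter_sd > 0:
        img_edges = img_edges + rng.normal(0.0, cohort.sync_jitter_sd,
                                           size=img_edges.size)
    keep = (img_edges >= 0) & (img_edges <= frame_times[-1])
    beh_edges, img_edges = beh_edges[keep], img_edges[keep]

    recording = SessionRecording(
        cell_ids=[p.cell_id for p in profiles], traces=traces,
        frame_times=frame_times, frame_rate=FRAME_RATE,
        sync_edges=img_edges)
    log = BehaviorLog(events=_events_frame(trials), sync_edges=beh_edges)
    return recording, log, trials_to_frame(trials), list(profiles)


def make_profiles(cohort: CohortSpec, rng: np.random.Generator,
                  prefix: str = "cell") -> list[TuningProfile]:
    """Draw one tuning profile per cell from the cohort's category mixture."""
    cats = list(cohort.category_mixture)
    props = np.array([cohort.category_mixture[c] for c in cats])
    drawn = rng.choice(len(cats), size=cohort.cells_per_mouse, p=props)
    return [
        TuningProfile.from_category(
            f"{prefix}{i:04d}", cats[j],
            baseline_rate=cohort.baseline_rate,
            excited_multiplier=cohort.excited_multiplier,
            inhibited_multiplier=cohort.inhibited_multiplier,
            amplitude_scale=cohort.amplitude_scale)
        for i, j in enumerate(drawn)
    ]


def generate_cohort(specs: list[CohortSpec],
                    task: TaskSpec) -> list[SessionBundle]:
    """Generate one session per mouse for each cohort spec.

    Per-mouse seeds are spawned deterministically from each spec's
    ``rng_seed`` and mouse index, so cohorts are reproducible and every
    session's randomness is distinct.
    """
    if not specs:
        raise ValueError("at least one cohort spec is required")
    labels = [s.group_label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels: {labels}")
    bundles: list[SessionBundle] = []
    for spec in specs:
        for j in range(spec.n_mice):
            child = np.random.SeedSequence(spec.rng_seed, spawn_key=(j,))
            rng = np.random.default_rng(child)
            profiles = make_profiles(spec, rng,
                                     prefix=f"{spec.group_label}_m{j}_c")
            rec, log, trials, profs = generate_session(task, profiles,
                                                       spec, seed=rng)
            bundles.append(SessionBundle(
                group_label=spec.group_label, mouse_index=j,
                recording=rec, log=log, trials=trials, profiles=profs))
    return bundles


def generate_motion_frames(n_frames: int, blob_displacement_schedule,
                           noise_amplitude: int = 0, seed=0,
                           frame_shape: tuple[int, int] = (48, 48),
                           blob_size: int = 5, blob_intensity: int = 100,
                           start: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Grayscale 8-bit frame stack with a square blob on a noisy background.

    ``blob_displacement_schedule`` gives the horizontal displacement (in
    pixels) applied *before* rendering each frame; its first entry is
    normally 0.  ``noise_amplitude`` must stay below the 10-gray-unit
    locomotion threshold so background noise never registers as motion.
    """
    schedule = np.asarray(blob_displacement_schedule, dtype=int)
    if schedule.shape != (n_frames,):
        raise ValueError("displacement schedule must have one entry per frame")
    if not 0 <= noise_amplitude < 10:
        raise ValueError("noise_amplitude must be in [0, 10) gray units")
    h, w = frame_shape
    rng = np.random.default_rng(seed)
    frames = np.zeros((n_frames, h, w), dtype=np.uint8)
    y, x = start
    for i in range(n_frames):
        x += int(schedule[i])
        if not (0 <= x and x + blob_size <= w and 0 <= y
                and y + blob_size <= h):
            raise ValueError(f"blob leaves the frame at frame {i}")
        if noise_amplitude:
            frames[i] = rng.integers(0, noise_amplitude + 1, size=(h, w),
                                     dtype=np.uint8)
        frames[i, y:y + blob_size, x:x + blob_size] = blob_intensity
    return frames
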