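"""Session data model, delimited-table I/O and clock synchronization.

A session couples a :class:`SessionRecording` (deconvolved calcium event
amplitudes, cells × frames at 20 Hz, on the *imaging* clock) with a
:class:`BehaviorLog` (operant events on the *behavioral* controller clock).
The two clocks are bridged by 5 s on/off sync pulses recorded on both
sides; :func:`fit_clock_map` fits an affine map (offset + drift) between
them and :func:`map_to_frames` converts behavioral event times to frame
indices.

All tables are delimited text (comma or tab, auto-detected, header
required):

``traces``
    one row per cell; first column ``cell_id``, remaining columns frame
    indices.
``events``
    columns ``time_s, event_code, port``.
``sync``
    columns ``edge_time_behavior_s, edge_time_imaging_s``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pericalc.task import FRAME_RATE

logger = logging.getLogger(__name__)

EVENT_CODES = frozenset({
    "trial_available", "initiation_poke", "cue_on",
    "side_poke_left", "side_poke_right", "reward_delivery", "iti_start",
})

SIDE_POKES = frozenset({"side_poke_left", "side_poke_right"})


class SchemaError(ValueError):
    """A table failed schema validation; the message names the field."""


@dataclass
class SessionRecording:
    """Deconvolved per-cell event-amplitude traces on the imaging clock.

    ``traces`` is cells × frames, non-negative; ``frame_times`` are evenly
    spaced at ``1/frame_rate``.  ``sync_edges`` holds the imaging-clock
    times of the shared sync-pulse edges (GPIO), if recorded.
    """

    cell_ids: list[str]
    traces: np.ndarray
    frame_times: np.ndarray
    frame_rate: float = FRAME_RATE
    sync_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.traces.ndim != 2:
            raise SchemaError("traces: expected a 2-D cells × frames matrix")
        if len(self.cell_ids) != self.traces.shape[0]:
            raise SchemaError("cell_ids: length does not match trace rows")
        if self.frame_times.shape[0] != self.traces.shape[1]:
            raise SchemaError("frame_times: length does not match trace columns")
        if np.any(self.traces < 0):
            raise SchemaError("traces: negative amplitude found")
        dt = np.diff(self.frame_times)
        if self.frame_times.size > 1 and (
                np.any(dt <= 0)
                or np.any(np.abs(dt - 1.0 / self.frame_rate) > 1e-6)):
            raise SchemaError(
                "frame_times: not strictly increasing at 1/frame_rate spacing")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass
class BehaviorLog:
    """Operant event stream and sync-pulse edges on the behavioral clock."""

    events: pd.DataFrame  # columns: time_s, event_code, port
    sync_edges: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        required = {"time_s", "event_code", "port"}
        missing = required - set(self.events.columns)
        if missing:
            raise SchemaError(f"events: missing column(s) {sorted(missing)}")
        self.sync_edges = np.asarray(self.sync_edges, dtype=float)
        t = self.events["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise SchemaError("events.time_s: times must be non-decreasing")
        unknown = set(self.events["event_code"]) - EVENT_CODES
        if unknown:
            raise SchemaError(f"events.event_code: unknown code(s) {sorted(unknown)}")
        # Every reward must follow at least one side poke.
        seen_poke = False
        for code in self.events["event_code"]:
            if code in SIDE_POKES:
                seen_poke = True
            elif code == "reward_delivery" and not seen_poke:
                raise SchemaError(
                    "events: reward_delivery before any side poke")


@dataclass(frozen=True)
class ClockMap:
    """Affine map from the behavioral clock to the imaging clock.

    ``imaging_time = offset + drift * behavior_time``.  ``residual_rms``
    is the root-mean-square residual of the sync-edge fit, seconds.
    """

    offset: float
    drift: float
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if not 0.9 < self.drift < 1.1:
            raise ValueError(f"drift {self.drift} outside plausible (0.9, 1.1)")

    def to_imaging(self, t):
        return self.offset + self.drift * np.asarray(t, dtype=float)

    def to_behavior(self, t):
        return (np.asarray(t, dtype=float) - self.offset) / self.drift

    @classmethod
    def identity(cls) -> "ClockMap":
        return cls(offset=0.0, drift=1.0, residual_rms=0.0)


class DesyncError(RuntimeError):
    """Sync-edge fit residual exceeded tolerance: clocks cannot be aligned."""


def fit_clock_map(behavior_edges, imaging_edges, *,
                  tolerance: float = 0.025, check: bool = True) -> ClockMap:
    """Least-squares affine fit between matched sync-pulse edge trains.

    Edges are matched by rank order.  If the trains differ in length
    (unpaired leading/trailing edges on one side), every contiguous
    alignment of the shorter train within the longer is tried and the one
    with minimal residual RMS is kept.

    Raises ``ValueError`` with fewer than 3 shared edges and
    :class:`DesyncError` when the residual RMS exceeds ``tolerance``
    (default 0.025 s, half a frame) and ``check`` is true.
    """
    b = np.sort(np.asarray(behavior_edges, dtype=float))
    m = np.sort(np.asarray(imaging_edges, dtype=float))
    n = min(b.size, m.size)
    if n < 3:
        raise ValueError("need at least 3 shared sync edges to fit a clock map")

    def _fit(bb, mm):
        drift, offset = np.polyfit(bb, mm, 1)
        resid = mm - (offset + drift * bb)
        return offset, drift, float(np.sqrt(np.mean(resid ** 2)))

    candidates = []
    for lag in range(abs(b.size - m.size) + 1):
        bb = b[lag:lag + n] if b.size >= m.size else b
        mm = m if b.size >= m.size else m[lag:lag + n]
        candidates.append(_fit(bb, mm))
    # A periodic pulse train makes the lag non-identifiable from the
    # residual alone (every shift by a whole period fits equally well);
    # real clock offsets are far below the pulse period, so among
    # near-minimal residuals prefer the smallest |offset|.
    min_rms = min(c[2] for c in candidates)
    offset, drift, rms = min(
        (c for c in candidates if c[2] <= min_rms + 1e-6),
        key=lambda c: abs(c[0]))
    if check and rms > tolerance:
        raise DesyncError(
            f"sync residual RMS {rms:.4f} s exceeds tolerance {tolerance} s; "
            "behavioral and imaging clocks appear desynchronized")
    return ClockMap(offset=offset, drift=drift, residual_rms=rms)


def map_to_frames(times_behavior, clock: ClockMap,
                  recording: SessionRecording) -> np.ndarray:
    """Convert behavioral-clock times to 0-based frame indices.

    ``frame = floor((imaging_time - first_frame_time) * frame_rate)``.
    Times mapping outside the recording are returned as ``-1`` and their
    count is logged.
    """
    t = clock.to_imaging(times_behavior)
    rel = (t - recording.frame_times[0]) * recording.frame_rate
    idx = np.floor(rel + 1e-9).astype(int)
    out = (idx < 0) | (idx >= recording.n_frames)
    if np.any(out):
        logger.warning("map_to_frames: %d event(s) outside the recording "
                       "were excluded", int(np.sum(out)))
        idx = np.where(out, -1, idx)
    return idx


# ---------------------------------------------------------------------------
# Delimited-table readers/writers


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def write_session(recording: SessionRecording, log: BehaviorLog,
                  directory, *, trials: pd.DataFrame | None = None,
                  profiles: pd.DataFrame | None = None) -> Path:
    """Write a session bundle as delimited tables plus a YAML manifest.

    Returns the path of the manifest (``session.yaml``).  Ground-truth
    tables (``trials``, ``profiles``) are written when given.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    traces = pd.DataFrame(recording.traces,
                          columns=[str(i) for i in range(recording.n_frames)])
    traces.insert(0, "cell_id", recording.cell_ids)
    traces.to_csv(directory / "traces.csv", index=False)

    log.events.to_csv(directory / "events.csv", index=False)

    n_beh = log.sync_edges.size
    img = recording.sync_edges
    img = np.full(n_beh, np.nan) if img is None else np.asarray(img, float)
    k = min(n_beh, img.size)
    sync = pd.DataFrame({
        "edge_time_behavior_s": log.sync_edges[:k],
        "edge_time_imaging_s": img[:k],
    })
    sync.to_csv(directory / "sync.csv", index=False)

    manifest = {
        "frame_rate": recording.frame_rate,
        "first_frame_time": float(recording.frame_times[0])
        if recording.n_frames else 0.0,
        "traces": "traces.csv",
        "events": "events.csv",
        "sync": "sync.csv",
    }
    if trials is not None:
        trials.to_csv(directory / "trials.csv", index=False)
        manifest["trials"] = "trials.csv"
    if profiles is not None:
        profiles.to_csv(directory / "profiles.csv", index=False)
        manifest["profiles"] = "profiles.csv"
    path = directory / "session.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def read_session(path) -> tuple[SessionRecording, BehaviorLog]:
    """Read a session bundle from a ``session.yaml`` manifest or directory.

    Validates all schema invariants; violations raise :class:`SchemaError`
    naming the offending field.
    """
    path = Path(path)
    if path.is_dir():
        path = path / "session.yaml"
    manifest = yaml.safe_load(path.read_text())
    base = path.parent

    traces_df = _read_table(base / manifest["traces"])
    if "cell_id" not in traces_df.columns:
        raise SchemaError("traces: missing column 'cell_id'")
    cell_ids = [str(c) for c in traces_df["cell_id"]]
    traces = traces_df.drop(columns="cell_id").to_numpy(dtype=float)

    frame_rate = float(manifest.get("frame_rate", FRAME_RATE))
    t0 = float(manifest.get("first_frame_time", 0.0))
    frame_times = t0 + np.arange(traces.shape[1]) / frame_rate

    events = _read_table(base / manifest["events"])
    events["port"] = events["port"].fillna("").astype(str)

    sync = _read_table(base / manifest["sync"])
    for col in ("edge_time_behavior_s", "edge_time_imaging_s"):
        if col not in sync.columns:
            raise SchemaError(f"sync: missing column '{col}'")
    sync_beh = sync["edge_time_behavior_s"].to_numpy(dtype=float)
    sync_img = sync["edge_time_imaging_s"].to_numpy(dtype=float)
    if np.all(np.isnan(sync_img)):
        sync_img = None

    recording = SessionRecording(cell_ids=cell_ids, traces=traces,
                                 frame_times=frame_times,
                                 frame_rate=frame_rate, sync_edges=sync_img)
    log = BehaviorLog(events=events, sync_edges=sync_beh)
    return recording, log
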