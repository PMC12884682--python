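"""Pixel-change locomotion index from overhead-video frame stacks.

Motion is quantified as the number of pixels whose grayscale intensity
changes by strictly more than a threshold (default 10 gray units, which
removes baseline pixel fluctuations) between consecutive frames.  The
per-frame-pair counts, sampled at the video rate (30 fps), are then
resampled onto the 20 Hz imaging time base by duration-weighted binning —
each source frame's count is spread uniformly over the frame's interval
and integrated over each imaging bin, so total motion is conserved
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from pericalc.session_io import ClockMap

DEFAULT_THRESHOLD = 10
IMAGING_BIN_RATE = 20.0


@dataclass
class MotionTrace:
    """Locomotion index on the imaging time base (20 bins/s)."""

    bin_times: np.ndarray       # bin start times, imaging clock, seconds
    motion_index: np.ndarray    # per-bin summed supra-threshold pixel counts
    source_fps: float = 30.0
    threshold: int = DEFAULT_THRESHOLD


def load_frames(path) -> np.ndarray:
    """Read a grayscale frame stack (multi-page TIFF, or a directory of
    image files sorted by name) into an (n, h, w) array."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = np.asarray(iio.imread(path))
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # RGB(A): collapse to grayscale by mean
        frames = frames[..., :3].mean(axis=-1)
    return frames


def motion_index(frames, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Per-consecutive-frame-pair count of pixels with |ΔI| > threshold.

    ``frames`` is an (n, h, w) stack of integer gray values, n >= 2.
    The inequality is strict: changes of exactly ``threshold`` gray units
    do not register.
    """
    stack = np.asarray(frames)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("expected an (n_frames >= 2, h, w) grayscale stack")
    diff = np.abs(np.diff(stack.astype(np.int32), axis=0))
    return np.count_nonzero(diff > threshold, axis=(1, 2)).astype(float)


def resample_motion(counts, source_fps: float = 30.0,
                    clock: ClockMap | None = None,
                    threshold: int = DEFAULT_THRESHOLD) -> MotionTrace:
    """Resample per-frame-pair motion counts onto 20 Hz imaging bins.

    Each count is attributed to its source-frame interval
    ``[i/fps, (i+1)/fps)`` (video clock), mapped to the imaging clock via
    ``clock`` (identity when omitted, i.e. video already aligned), and
    spread over the overlapping imaging bins in proportion to overlap
    duration.  The bin sums conserve the total count exactly.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("counts must be a non-empty 1-D array")
    if not np.all(np.isfinite(c)):
        raise ValueError("counts must be finite")
    if clock is None:
        clock = ClockMap.identity()
    starts = clock.to_imaging(np.arange(c.size) / source_fps)
    ends = clock.to_imaging((np.arange(c.size) + 1) / source_fps)

    bin_w = 1.0 / IMAGING_BIN_RATE
    first = int(np.floor(starts[0] / bin_w))
    last = int(np.ceil(ends[-1] / bin_w))
    out = np.zeros(last - first)
    for s, e, ci in zip(starts, ends, c):
        if ci == 0.0:
            continue
        frame_dur = e - s
        b0 = int(np.floor(s / bin_w))
        b1 = int(np.ceil(e / bin_w))
        for b in range(b0, b1):
            lo = max(s, b * bin_w)
            hi = min(e, (b + 1) * bin_w)
            if hi > lo:
                out[b - first] += ci * (hi - lo) / frame_dur
    times = (np.arange(first, last)) * bin_w
    return MotionTrace(bin_times=times, motion_index=out,
                       source_fps=source_fps, threshold=threshold)
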