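"""Operant task structure and the trial-epoch vocabulary.

Two self-initiated two-choice tasks are modeled.  In the cue-guided task a
side cue lights at trial initiation and the mouse must respond within a
short window (1.5 s).  In the delay (waiting) task a 3 s delay separates
initiation from cue onset; side pokes during the delay are "premature"
responses that are counted but never change the trial outcome.

Within-trial epochs are named by single letters:

=====  =============================================================
label  window
=====  =============================================================
T      2 s preceding trial initiation
C      trial initiation (cue onset) through the cue response
D      the 3 s delay between initiation and cue onset (delay task)
R      0–3 s after reward delivery
P      3–6 s after reward delivery
=====  =============================================================

The paired baseline is the last 6 s of the intertrial interval (ITI)
preceding each trial's availability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: Canonical ordering of epoch letters in mixed-selectivity categories.
CANONICAL_EPOCHS = "TCDRP"

_CATEGORY_RE = re.compile(r"([TCDRP])([+-])")

FRAME_RATE = 20.0  #: imaging frame rate, Hz


@dataclass(frozen=True)
class TaskSpec:
    """Parameters of one operant task variant.

    Parameters
    ----------
    task_kind:
        ``"cue_guided"`` (1.5 s cued response window at initiation) or
        ``"delay"`` (3 s enforced delay between initiation and cue).
    cue_duration:
        Length of the cued response window in seconds.  For the delay task
        this is the response window that follows the delay.
    delay_duration:
        Delay between initiation and cue onset (delay task only), seconds.
    iti_mean:
        Mean intertrial interval in seconds.  The field value is 45 s;
        fast test profiles may go as low as ~8 s.
    session_length:
        Total session duration in seconds (both clocks nominally).
    reward_epoch:
        Length of the reward (R) epoch after reward delivery, seconds.
    post_reward_epoch:
        ``(start, end)`` offsets of the post-reward (P) epoch relative to
        reward delivery, seconds.
    baseline_duration:
        Length of the per-trial ITI baseline window, seconds.
    init_latency:
        ``(lo, hi)`` of the uniform latency from trial availability to the
        initiation poke used by the synthetic generator, seconds.
    delay_include_cue_epoch:
        If True (default) the delay task uses five epochs
        (T, C, D, R, P); if False the four-epoch set (T, D, R, P).
    """

    task_kind: str = "cue_guided"
    cue_duration: float = 1.5
    delay_duration: float = 3.0
    iti_mean: float = 45.0
    iti_distribution: str = "uniform"
    session_length: float = 2400.0
    reward_epoch: float = 3.0
    post_reward_epoch: tuple[float, float] = (3.0, 6.0)
    baseline_duration: float = 6.0
    init_latency: tuple[float, float] = (2.0, 4.0)
    delay_include_cue_epoch: bool = True

    def __post_init__(self) -> None:
        if self.task_kind not in ("cue_guided", "delay"):
            raise ValueError(f"unknown task_kind: {self.task_kind!r}")
        for name in ("cue_duration", "delay_duration", "iti_mean",
                     "session_length", "reward_epoch", "baseline_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.iti_distribution != "uniform":
            raise ValueError("only the uniform ITI distribution is supported")
        lo, hi = self.post_reward_epoch
        if not 0 <= lo < hi:
            raise ValueError("post_reward_epoch must satisfy 0 <= start < end")
        lo, hi = self.init_latency
        if not 0 <= lo <= hi:
            raise ValueError("init_latency must satisfy 0 <= lo <= hi")
        if self.iti_bounds[1] <= self.baseline_duration:
            raise ValueError(
                "1.5 * iti_mean must exceed the 6 s baseline window")

    @property
    def iti_bounds(self) -> tuple[float, float]:
        """Uniform ITI bounds: [max(0.5·mean, baseline), 1.5·mean] s."""
        return (max(0.5 * self.iti_mean, self.baseline_duration),
                1.5 * self.iti_mean)

    @property
    def epoch_labels(self) -> list[str]:
        """Epoch letters for this task, in canonical (T C D R P) order."""
        if self.task_kind == "cue_guided":
            labels = "TCRP"
        elif self.delay_include_cue_epoch:
            labels = "TCDRP"
        else:
            labels = "TDRP"
        return list(labels)

    @property
    def max_trial_span(self) -> float:
        """Upper bound on availability → end-of-post-reward span, seconds."""
        span = self.init_latency[1] + self.cue_duration + self.post_reward_epoch[1]
        if self.task_kind == "delay":
            span += self.delay_duration
        return span


def parse_category(category: str) -> list[tuple[str, str]]:
    """Parse a mixed-selectivity category string into (epoch, sign) pairs.

    ``""`` (nonresponsive) parses to an empty list.  Raises ``ValueError``
    on malformed strings or repeated epochs.
    """
    pairs = _CATEGORY_RE.findall(category)
    if "".join(e + s for e, s in pairs) != category:
        raise ValueError(f"malformed category string: {category!r}")
    epochs = [e for e, _ in pairs]
    if len(set(epochs)) != len(epochs):
        raise ValueError(f"epoch repeated in category: {category!r}")
    return pairs


def canonical_category(pairs: list[tuple[str, str]]) -> str:
    """Compose (epoch, sign) pairs into canonical T→C→D→R→P order."""
    order = {e: i for i, e in enumerate(CANONICAL_EPOCHS)}
    return "".join(e + s for e, s in sorted(pairs, key=lambda p: order[p[0]]))
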