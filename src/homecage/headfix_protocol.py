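"""Head-fixation training state machines and release logic.

Training proceeds in two subprotocols.  *Headport entry* lures the mouse to
the headport: the lickport starts inside the cage, retracts 3 mm for every 20
rewarded licks until it sits ~14 mm from the headport, re-extends if no licks
occur for 12 h, and hands over to fixation training after the headbar has
triggered the mechanical switches 30 times.  *Head fixation* clamps the
headbar whenever the switches are triggered; fixations end by time-up
(scheduled duration elapsed), escape (the mouse withdraws before the clamp
holds) or self-release (load-cell reading crosses an adaptive threshold).
The scheduled duration starts at 3 s and grows by 2 s per 20 time-up
releases; the clamp switches from soft (1.78 bar) to hard (2.78 bar after
the first 2 s) once the duration reaches 10 s; training completes at 30 s
(extended to 60 s after the task's delay stage completes).

Self-release thresholds start at (-1, 30) g and adapt on the last 20
fixations: >90% self-releases widens the band by 2 g on each side, <5%
narrows it likewise, never below a 10 g width.

The load-sensing platform doubles as a scale: the mode of the 24 h weight
histogram estimates body weight.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ReleaseType",
    "Subprotocol",
    "ClampMode",
    "HeadfixState",
    "FixationEvent",
    "LoadSample",
    "InsufficientDataError",
    "step_headport_entry",
    "step_fixation_training",
    "update_release_thresholds",
    "resolve_release",
    "estimate_body_weight",
]

LICKPORT_STEP_MM = 3.0
LICKPORT_MAX_MM = 14.0
REWARDED_LICKS_PER_STEP = 20
SWITCH_TRIGGERS_TO_ADVANCE = 30
REWARDS_PER_SPOUT = 3
NO_LICK_REEXTEND_HOURS = 12.0

FIXATION_START_S = 3.0
FIXATION_INCREMENT_S = 2.0
TIMEUPS_PER_INCREMENT = 20
HARD_CLAMP_AT_S = 10.0
TRAINING_CAP_S = 30.0
EXTENSION_CAP_S = 60.0
SOFT_PRESSURE_BAR = 1.78
HARD_PRESSURE_BAR = 2.78

THRESHOLDS_INIT_G = (-1.0, 30.0)
THRESHOLD_STEP_G = 2.0
ADAPT_BUFFER = 20
WIDEN_ABOVE = 0.90
NARROW_BELOW = 0.05
MIN_BAND_WIDTH_G = 10.0

ESCAPE_WINDOW_S = 0.2  # switches must stay engaged this long for the clamp to hold
LOAD_SAMPLE_HZ = 20.0


class ReleaseType(str, Enum):
    TIME_UP = "time_up"
    ESCAPE = "escape"
    SELF_RELEASE = "self_release"


class Subprotocol(str, Enum):
    HEADPORT_ENTRY = "headport_entry"
    HEAD_FIXATION = "head_fixation"
    COMPLETE = "complete"


class ClampMode(str, Enum):
    SOFT = "soft"
    HARD = "hard"


class InsufficientDataError(ValueError):
    """Raised when a stream is too short to support the requested estimate."""


@dataclass
class HeadfixState:
    subprotocol: Subprotocol = Subprotocol.HEADPORT_ENTRY
    lickport_distance_mm: float = 0.0
    rewarded_licks_since_retraction: int = 0
    switch_trigger_count: int = 0
    rewarded_spout_is_left: bool = True
    rewards_on_current_spout: int = 0
    fixation_duration_s: float = FIXATION_START_S
    timeup_count_since_increment: int = 0
    duration_cap_s: float = TRAINING_CAP_S
    release_thresholds_g: tuple[float, float] = THRESHOLDS_INIT_G
    recent_releases: deque = field(default_factory=lambda: deque(maxlen=ADAPT_BUFFER))

    @property
    def clamp_mode(self) -> ClampMode:
        return ClampMode.HARD if self.fixation_duration_s >= HARD_CLAMP_AT_S else ClampMode.SOFT

    def clamp_pressure_bar(self, t_in_fixation: float) -> float:
        """Piston pressure at time t into a fixation."""
        if self.clamp_mode is ClampMode.SOFT or t_in_fixation < 2.0:
            return SOFT_PRESSURE_BAR
        return HARD_PRESSURE_BAR

    def extend_cap(self) -> None:
        """Raise the duration cap from 30 to 60 s (post-task extension)."""
        self.duration_cap_s = EXTENSION_CAP_S
        if self.subprotocol is Subprotocol.COMPLETE:
            self.subprotocol = Subprotocol.HEAD_FIXATION


@dataclass(frozen=True)
class FixationEvent:
    start_time: float
    end_time: float
    scheduled_duration: float
    release_type: ReleaseType
    thresholds_at_release: tuple[float, float]
    n_trials_completed: int = 0
    first_trial_index: Optional[int] = None
    is_dark_cycle: bool = False

    def to_dict(self) -> dict:
        return {
            "start_time": self.start_time,
            "end_time": self.end_time,
            "scheduled_duration": self.scheduled_duration,
            "release_type": self.release_type.value,
            "thresholds_at_release": list(self.thresholds_at_release),
            "n_trials_completed": self.n_trials_completed,
            "first_trial_index": self.first_trial_index,
            "is_dark_cycle": self.is_dark_cycle,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FixationEvent":
        return cls(
            start_time=float(d["start_time"]),
            end_time=float(d["end_time"]),
            scheduled_duration=float(d["scheduled_duration"]),
            release_type=ReleaseType(d["release_type"]),
            thresholds_at_release=tuple(d["thresholds_at_release"]),
            n_trials_completed=int(d.get("n_trials_completed", 0)),
            first_trial_index=d.get("first_trial_index"),
            is_dark_cycle=bool(d.get("is_dark_cycle", False)),
        )


@dataclass(frozen=True)
class LoadSample:
    time: float
    weight_g: float


def step_headport_entry(state: HeadfixState, event: str) -> HeadfixState:
    """Advance the headport-entry subprotocol by one event.

    Events: ``rewarded_lick``, ``switch_trigger``, ``no_lick_12h``.
    Mutates and returns ``state``.
    """
    if state.subprotocol is not Subprotocol.HEADPORT_ENTRY:
        raise ValueError(f"headport-entry event {event!r} after subprotocol "
                         f"{state.subprotocol.value}")
    if event == "rewarded_lick":
        state.rewarded_licks_since_retraction += 1
        state.rewards_on_current_spout += 1
        if state.rewards_on_current_spout >= REWARDS_PER_SPOUT:
            state.rewarded_spout_is_left = not state.rewarded_spout_is_left
            state.rewards_on_current_spout = 0
        if state.rewarded_licks_since_retraction >= REWARDED_LICKS_PER_STEP:
            state.rewarded_licks_since_retraction = 0
            state.lickport_distance_mm = min(
                LICKPORT_MAX_MM, state.lickport_distance_mm + LICKPORT_STEP_MM
            )
    elif event == "switch_trigger":
        state.switch_trigger_count += 1
        if state.switch_trigger_count >= SWITCH_TRIGGERS_TO_ADVANCE:
            state.subprotocol = Subprotocol.HEAD_FIXATION
    elif event == "no_lick_12h":
        state.lickport_distance_mm = 0.0
        state.rewarded_licks_since_retraction = 0
    else:
        raise ValueError(f"unknown headport-entry event {event!r}")
    return state


def step_fixation_training(state: HeadfixState, release: ReleaseType) -> HeadfixState:
    """Advance the fixation-duration schedule by one completed fixation.

    Only time-up releases count toward the 20-fixation increment; escapes and
    self-releases enter the threshold-adaptation buffer but not the duration
    schedule.  Completion is duration >= cap (the 3,5,...,29,31 schedule first
    crosses 30 s at 31 s).
    """
    if state.subprotocol is Subprotocol.HEADPORT_ENTRY:
        raise ValueError("fixation release before the head-fixation subprotocol")
    state.recent_releases.append(release)
    if len(state.recent_releases) == ADAPT_BUFFER:
        state.release_thresholds_g = update_release_thresholds(
            list(state.recent_releases), state.release_thresholds_g
        )
    if release is ReleaseType.TIME_UP and state.subprotocol is Subprotocol.HEAD_FIXATION:
        state.timeup_count_since_increment += 1
        if state.timeup_count_since_increment >= TIMEUPS_PER_INCREMENT:
            state.timeup_count_since_increment = 0
            state.fixation_duration_s += FIXATION_INCREMENT_S
            if state.fixation_duration_s >= state.duration_cap_s:
                state.subprotocol = Subprotocol.COMPLETE
    return state


def update_release_thresholds(
    recent: Sequence[ReleaseType], thresholds: tuple[float, float]
) -> tuple[float, float]:
    """Adapt self-release thresholds from the last 20 release types.

    Widen by 2 g per side when self-releases exceed 90% of the buffer, narrow
    when below 5%; the band never narrows below 10 g.  Escapes count as
    non-self releases.
    """
    if len(recent) != ADAPT_BUFFER:
        raise ValueError(f"threshold adaptation needs exactly {ADAPT_BUFFER} releases")
    lower, upper = thresholds
    frac = sum(r is ReleaseType.SELF_RELEASE for r in recent) / len(recent)
    if frac > WIDEN_ABOVE:
        return (lower - THRESHOLD_STEP_G, upper + THRESHOLD_STEP_G)
    if frac < NARROW_BELOW:
        if (upper - THRESHOLD_STEP_G) - (lower + THRESHOLD_STEP_G) >= MIN_BAND_WIDTH_G:
            return (lower + THRESHOLD_STEP_G, upper - THRESHOLD_STEP_G)
        return thresholds
    return thresholds


def resolve_release(
    load: Iterable[LoadSample],
    switch_disengage_time: Optional[float],
    scheduled_duration: float,
    thresholds: tuple[float, float],
) -> tuple[ReleaseType, float]:
    """Determine how and when a fixation ends.

    Candidates, earliest wins: escape if the switches disengage within the
    first 0.2 s (before the clamp holds); self-release at the first load
    sample outside (lower, upper); time-up at the scheduled duration.
    Times are seconds from clamp onset.
    """
    lower, upper = thresholds
    t_self = None
    for s in load:
        if s.time >= scheduled_duration:
            break
        if s.weight_g < lower or s.weight_g > upper:
            t_self = s.time
            break
    candidates: list[tuple[float, int, ReleaseType]] = [
        (scheduled_duration, 2, ReleaseType.TIME_UP)
    ]
    if switch_disengage_time is not None and switch_disengage_time < ESCAPE_WINDOW_S:
        candidates.append((switch_disengage_time, 0, ReleaseType.ESCAPE))
    if t_self is not None:
        candidates.append((t_self, 1, ReleaseType.SELF_RELEASE))
    t, _, rtype = min(candidates)
    return rtype, t


def estimate_body_weight(
    samples: Iterable[LoadSample],
    bin_width_g: float = 0.1,
    on_platform_floor_g: float = 5.0,
    min_samples: int = 100,
) -> float:
    """Body weight as the mode of the on-platform weight histogram.

    Samples at or below the on-platform floor (empty platform, partial steps)
    are discarded; the estimate is the center of the tallest ``bin_width_g``
    histogram bin.
    """
    weights = np.asarray([s.weight_g for s in samples], dtype=float)
    weights = weights[weights > on_platform_floor_g]
    if weights.size < min_samples:
        raise InsufficientDataError(
            f"need >= {min_samples} on-platform samples, got {weights.size}"
        )
    lo = np.floor(weights.min() / bin_width_g) * bin_width_g
    hi = np.ceil(weights.max() / bin_width_g) * bin_width_g + bin_width_g
    edges = np.arange(lo, hi + bin_width_g / 2, bin_width_g)
    counts, edges = np.histogram(weights, bins=edges)
    k = int(np.argmax(counts))
    return float((edges[k] + edges[k + 1]) / 2)
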