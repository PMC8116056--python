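"""Single-trial state machine for the delayed-response tactile decision task.

A trial consists of a sample epoch (1.3 s: 0.2 s pole travel, 1.0 s
presentation, 0.1 s into retraction), a delay epoch (0.2-1.3 s depending on
the training stage), an auditory go cue (0.1 s), a response window (1.5 s)
and an inter-trial interval (2.5 s).  The mouse reports pole position by
licking the left or right spout; only the first lick after the go cue counts
as the choice.  In the delay-enforcing stage, a lick before the go cue pauses
the trial for 0.1 s and restarts the epoch in which the lick occurred.

Optogenetic trials carry a photostimulus: a 40 Hz sinusoid lasting 1.3 s
(including a 100 ms linear offset ramp) aligned to the start of the sample,
delay or response epoch.  A 10 Hz masking flash covers the sample epoch
through the end of the response epoch on every trial of an optogenetic
session, stimulated or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "TIME_RESOLUTION",
    "TrialType",
    "Spout",
    "Choice",
    "Outcome",
    "Stage",
    "Contingency",
    "StimEpoch",
    "PolePosition",
    "TrialConfig",
    "EpochTimeline",
    "TrialRecord",
    "LickPlan",
    "build_timeline",
    "register_choice",
    "apply_early_lick_policy",
    "run_trial",
    "correct_choice_for",
    "pole_position_for",
]

# Task-controller tick, seconds.  All event times are quantized to this grid.
TIME_RESOLUTION = 1e-4

PHOTOSTIM_DURATION = 1.3  # s, fixed regardless of epoch length
PHOTOSTIM_RAMP = 0.1  # s linear ramp at stimulus offset
MASKING_FLASH_HZ = 10.0


def quantize(t: float) -> float:
    """Snap a time to the controller tick grid."""
    return round(round(t / TIME_RESOLUTION) * TIME_RESOLUTION, 6)


class TrialType(str, Enum):
    LICK_LEFT = "lick_left"
    LICK_RIGHT = "lick_right"


class Spout(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Choice(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    IGNORE = "ignore"


class Outcome(str, Enum):
    CORRECT = "correct"
    ERROR = "error"
    IGNORE = "ignore"


class Stage(str, Enum):
    DIRECTIONAL = "directional"
    DISCRIMINATION = "discrimination"
    DELAY = "delay"
    COMPLETE = "complete"


class Contingency(str, Enum):
    STANDARD = "standard"
    REVERSED = "reversed"


class StimEpoch(str, Enum):
    SAMPLE = "sample"
    DELAY = "delay"
    RESPONSE = "response"


class PolePosition(str, Enum):
    ANTERIOR = "anterior"
    POSTERIOR = "posterior"


def correct_choice_for(trial_type: TrialType, contingency: Contingency = Contingency.STANDARD) -> Choice:
    """Rewarded lick direction for a trial type.

    The trial type names the rewarded direction, so the mapping does not
    depend on contingency; contingency determines which pole position the
    trial type corresponds to (see :func:`pole_position_for`).
    """
    return Choice.LEFT if trial_type is TrialType.LICK_LEFT else Choice.RIGHT


def pole_position_for(trial_type: TrialType, contingency: Contingency) -> PolePosition:
    """Pole position presented on a trial.

    Standard contingency: anterior pole -> lick left, posterior -> lick right.
    Reversed contingency inverts the mapping.
    """
    standard_left = PolePosition.ANTERIOR
    standard_right = PolePosition.POSTERIOR
    if contingency is Contingency.STANDARD:
        return standard_left if trial_type is TrialType.LICK_LEFT else standard_right
    return standard_right if trial_type is TrialType.LICK_LEFT else standard_left


@dataclass(frozen=True)
class TrialConfig:
    """Timing parameters of one trial, in seconds."""

    sample_duration: float = 1.3
    delay_duration: float = 1.3
    go_cue_duration: float = 0.1
    response_window: float = 1.5
    inter_trial_interval: float = 2.5
    error_timeout: float = 4.0  # 2 s in the directional stage, 4 s afterwards
    early_lick_pause: float = 0.1
    enforce_delay: bool = True
    reward_volume_ul: float = 2.5  # 2-3 uL per reward

    def validate(self) -> None:
        for name in (
            "sample_duration",
            "delay_duration",
            "go_cue_duration",
            "response_window",
            "inter_trial_interval",
            "error_timeout",
            "early_lick_pause",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class EpochTimeline:
    """Epoch boundaries of one trial, seconds from trial start."""

    sample_start: float
    sample_end: float
    delay_end: float
    go_time: float  # == delay_end: the go cue starts the response epoch
    response_end: float
    trial_end: float
    photostim_window: Optional[tuple[float, float]] = None
    photostim_ramp_start: Optional[float] = None
    masking_flash: Optional[tuple[float, float]] = None

    @property
    def delay_start(self) -> float:
        return self.sample_end


@dataclass
class TrialRecord:
    """One completed behavioral trial."""

    trial_index: int
    trial_type: TrialType
    pole_position: PolePosition
    contingency: Contingency
    stage: Stage
    delay_duration: float
    lick_events: list[tuple[float, Spout]]
    choice: Choice
    outcome: Outcome
    early_lick_count: int = 0
    photostim: Optional[object] = None  # task_protocol.PhotostimAssignment
    autoassist_flags: set[str] = field(default_factory=set)
    rewarded: bool = False
    timeline: Optional[EpochTimeline] = None

    def to_dict(self) -> dict:
        stim = None
        if self.photostim is not None:
            stim = {
                "epoch": str(getattr(self.photostim, "epoch")),
                "intensity_mw_mm2": float(getattr(self.photostim, "intensity_mw_mm2")),
            }
        return {
            "trial_index": self.trial_index,
            "trial_type": self.trial_type.value,
            "pole_position": self.pole_position.value,
            "contingency": self.contingency.value,
            "stage": self.stage.value,
            "delay_duration": self.delay_duration,
            "lick_events": [[t, s.value] for t, s in self.lick_events],
            "choice": self.choice.value,
            "outcome": self.outcome.value,
            "early_lick_count": self.early_lick_count,
            "photostim": stim,
            "autoassist_flags": sorted(self.autoassist_flags),
            "rewarded": self.rewarded,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        from .task_protocol import PhotostimAssignment  # local import, no cycle at module load

        stim = None
        if d.get("photostim") is not None:
            epoch = d["photostim"]["epoch"]
            epoch = epoch.split(".")[-1].lower() if "." in epoch else epoch
            stim = PhotostimAssignment(
                epoch=StimEpoch(epoch),
                intensity_mw_mm2=d["photostim"]["intensity_mw_mm2"],
            )
        return cls(
            trial_index=int(d["trial_index"]),
            trial_type=TrialType(d["trial_type"]),
            pole_position=PolePosition(d["pole_position"]),
            contingency=Contingency(d["contingency"]),
            stage=Stage(d["stage"]),
            delay_duration=float(d["delay_duration"]),
            lick_events=[(float(t), Spout(s)) for t, s in d["lick_events"]],
            choice=Choice(d["choice"]),
            outcome=Outcome(d["outcome"]),
            early_lick_count=int(d.get("early_lick_count", 0)),
            photostim=stim,
            autoassist_flags=set(d.get("autoassist_flags", [])),
            rewarded=bool(d.get("rewarded", False)),
        )


@dataclass(frozen=True)
class LickPlan:
    """Scripted lick behavior for one trial.

    ``early_licks`` are intended pre-go licks on the nominal timeline; a
    planned early lick is emitted only if its time is still before the go cue
    on the (possibly restarted) running timeline.  ``response`` is the
    (latency-from-go, spout) of the choice lick, or None to ignore the trial.
    """

    early_licks: tuple[tuple[float, Spout], ...] = ()
    response: Optional[tuple[float, Spout]] = None


def build_timeline(config: TrialConfig, stim=None) -> EpochTimeline:
    """Lay out epoch boundaries for one trial.

    ``stim`` may be any object with an ``epoch`` attribute naming the
    photostimulated epoch (sample, delay or response).  The photostimulus
    lasts exactly 1.3 s from the start of its epoch regardless of the epoch's
    own length, so on short training delays it overruns into the response
    epoch; the overlap is preserved and visible in the returned window.
    """
    config.validate()
    sample_start = 0.0
    sample_end = quantize(config.sample_duration)
    delay_end = quantize(sample_end + config.delay_duration)
    go_time = delay_end
    response_end = quantize(go_time + config.go_cue_duration + config.response_window)
    trial_end = quantize(response_end + config.inter_trial_interval)

    photostim_window = None
    ramp_start = None
    if stim is not None:
        epoch = StimEpoch(getattr(stim, "epoch"))
        starts = {
            StimEpoch.SAMPLE: sample_start,
            StimEpoch.DELAY: sample_end,
            StimEpoch.RESPONSE: go_time,
        }
        start = starts[epoch]
        photostim_window = (start, quantize(start + PHOTOSTIM_DURATION))
        ramp_start = quantize(photostim_window[1] - PHOTOSTIM_RAMP)

    masking_flash = (sample_start, response_end)
    return EpochTimeline(
        sample_start=sample_start,
        sample_end=sample_end,
        delay_end=delay_end,
        go_time=go_time,
        response_end=response_end,
        trial_end=trial_end,
        photostim_window=photostim_window,
        photostim_ramp_start=ramp_start,
        masking_flash=masking_flash,
    )


def register_choice(licks: Sequence[tuple[float, Spout]], timeline: EpochTimeline,
                    response_window: float = 1.5) -> Choice:
    """First lick strictly after the go cue, within the response window.

    The window is the half-open interval (go, go + response_window]; a lick
    exactly at the go cue is treated as pre-go.  No qualifying lick -> ignore.
    """
    lo = timeline.go_time
    hi = timeline.go_time + response_window
    for t, spout in licks:
        if lo < t <= hi:
            return Choice.LEFT if spout is Spout.LEFT else Choice.RIGHT
    return Choice.IGNORE


def apply_early_lick_policy(timeline: EpochTimeline, lick_time: float, stage: Stage,
                            config: TrialConfig) -> tuple[EpochTimeline, bool]:
    """Handle a lick before the go cue.

    In the delay stage the trial pauses for ``early_lick_pause`` and resumes
    from the beginning of the epoch (sample or delay) in which the lick
    occurred.  In earlier stages the mouse is free to lick at any time and
    the timeline is unchanged.  Returns (timeline, restarted).
    """
    if lick_time >= timeline.go_time:
        raise ValueError("apply_early_lick_policy requires a pre-go lick")
    if stage is not Stage.DELAY or not config.enforce_delay:
        return timeline, False

    resume = quantize(lick_time + config.early_lick_pause)
    if lick_time < timeline.sample_end:
        # replay the sample epoch from scratch after the pause
        sample_end = quantize(resume + config.sample_duration)
        delay_end = quantize(sample_end + config.delay_duration)
    else:
        # lick in the delay: only the delay epoch restarts
        sample_end = timeline.sample_end
        delay_end = quantize(resume + config.delay_duration)
    return _shift_tail(timeline, sample_end, delay_end, config), True


def _shift_tail(timeline: EpochTimeline, sample_end: float, delay_end: float,
                config: TrialConfig) -> EpochTimeline:
    go_time = delay_end
    response_end = quantize(go_time + config.go_cue_duration + config.response_window)
    trial_end = quantize(response_end + config.inter_trial_interval)
    masking = (timeline.sample_start, response_end)
    return replace(
        timeline,
        sample_end=sample_end,
        delay_end=delay_end,
        go_time=go_time,
        response_end=response_end,
        trial_end=trial_end,
        masking_flash=masking,
    )


def run_trial(
    config: TrialConfig,
    behavior: LickPlan,
    trial_type: TrialType,
    stage: Stage = Stage.DELAY,
    contingency: Contingency = Contingency.STANDARD,
    stim=None,
    trial_index: int = 0,
) -> TrialRecord:
    """Execute one trial against a scripted lick plan.

    Early licks restart epochs per the stage policy; the choice is the first
    post-go lick; a correct choice dispenses the reward and an error appends
    the stage-specific timeout (2 s directional, 4 s later stages) before the
    inter-trial interval.
    """
    config.validate()
    timeline = build_timeline(config, stim)
    lick_events: list[tuple[float, Spout]] = []
    early_lick_count = 0

    for t, spout in behavior.early_licks:
        t = quantize(t)
        lick_events.append((t, spout))
        if t >= timeline.go_time:
            continue  # epoch restarts pushed the go cue earlier than this lick
        timeline, restarted = apply_early_lick_policy(timeline, t, stage, config)
        if restarted:
            early_lick_count += 1

    if behavior.response is not None:
        latency, spout = behavior.response
        lick_events.append((quantize(timeline.go_time + latency), spout))

    lick_events.sort(key=lambda e: e[0])
    choice = register_choice(lick_events, timeline, config.response_window)

    if choice is Choice.IGNORE:
        outcome = Outcome.IGNORE
    elif choice is correct_choice_for(trial_type, contingency):
        outcome = Outcome.CORRECT
    else:
        outcome = Outcome.ERROR

    rewarded = outcome is Outcome.CORRECT
    if outcome is Outcome.ERROR:
        timeout = 2.0 if stage is Stage.DIRECTIONAL else config.error_timeout
        timeline = replace(timeline, trial_end=quantize(timeline.response_end + timeout
                                                        + config.inter_trial_interval))

    return TrialRecord(
        trial_index=trial_index,
        trial_type=trial_type,
        pole_position=pole_position_for(trial_type, contingency),
        contingency=contingency,
        stage=stage,
        delay_duration=config.delay_duration,
        lick_events=lick_events,
        choice=choice,
        outcome=outcome,
        early_lick_count=early_lick_count,
        photostim=stim,
        rewarded=rewarded,
        timeline=timeline,
    )
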