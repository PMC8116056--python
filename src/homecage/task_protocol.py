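"""Task-training protocol: stage progression, trial scheduling and assists.

Task training shapes behavior in three stages.  *Directional licking*
presents one trial type in blocks, switching sides after three correct
trials; it advances at >=70% correct over the last 30 scored trials.
*Discrimination* randomizes trial types and advances at >=75%.  *Delay*
enforces a memory period that grows from 0.3 s to 1.3 s in 0.2 s steps, one
step per 70% criterion pass; the stage (and task training) completes at
1.3 s.

Four auto-assist programs counter side biases during discrimination and
delay training: the lickport shifts toward the non-preferred spout when the
per-type performance gap exceeds 30% over 50 trials (or 80% over 20); five
consecutive errors in one type trigger a free reward on that type's next
trial; the worse-performing type (last 30 trials) is presented more
frequently; three consecutive errors force the same type until two corrects.

Contingency-reversal training drops the delay stage and flips the
pole-position -> lick-direction mapping every time performance exceeds 80%
over 100 trials.  The optogenetics protocol tags a random 10% of trials with
a photostimulus in a chosen epoch at a randomly drawn intensity.

Scored performance counts correct and error trials only; ignores never enter
criterion windows, and they break consecutive-error runs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .trial_engine import Contingency, Outcome, Spout, Stage, StimEpoch, TrialType

__all__ = [
    "PhotostimAssignment",
    "TaskState",
    "AssistAction",
    "MoveLickport",
    "FreeReward",
    "Reweight",
    "ForcedRepeat",
    "record_outcome",
    "advance_stage",
    "select_trial_type",
    "evaluate_autoassist",
    "check_contingency_reversal",
    "assign_photostim",
]

DIRECTIONAL_CRITERION = 0.70
DIRECTIONAL_WINDOW = 30
DISCRIMINATION_CRITERION = 0.75
DELAY_CRITERION = 0.70
DELAY_START_S = 0.3
DELAY_STEP_S = 0.2
DELAY_FINAL_S = 1.3
BLOCK_CORRECTS_TO_SWITCH = 3
REVERSAL_WINDOW = 100
REVERSAL_CRITERION = 0.80  # strictly greater than
BIAS_GAP_50 = 0.30
BIAS_GAP_20 = 0.80
FREE_REWARD_ERRORS = 5
FORCED_REPEAT_ERRORS = 3
FORCED_REPEAT_CORRECTS = 2
REWEIGHT_WINDOW = 30
PHOTOSTIM_PROBABILITY = 0.10


@dataclass(frozen=True)
class PhotostimAssignment:
    """Photostimulus tag for one trial: epoch and light intensity."""

    epoch: StimEpoch
    intensity_mw_mm2: float


@dataclass(frozen=True)
class MoveLickport:
    toward: Spout  # bring this spout closer (the non-preferred side)
    step_mm: float = 1.0


@dataclass(frozen=True)
class FreeReward:
    trial_type: TrialType


@dataclass(frozen=True)
class Reweight:
    p_left: float
    p_right: float


@dataclass(frozen=True)
class ForcedRepeat:
    trial_type: TrialType


AssistAction = Union[MoveLickport, FreeReward, Reweight, ForcedRepeat]

HistoryEntry = tuple[TrialType, Outcome]


@dataclass
class TaskState:
    """Controller state for task training.

    ``history`` keeps the recent (trial_type, outcome) pairs including
    ignores; criterion windows are evaluated on scored entries only and are
    reset (via ``scored_since_reset``) after every stage change, delay
    increment or contingency flip.
    """

    stage: Stage = Stage.DIRECTIONAL
    contingency: Contingency = Contingency.STANDARD
    delay_duration: float = 0.2  # unenforced short delay before the delay stage
    trial_type_probabilities: tuple[float, float] = (0.5, 0.5)  # (p_left, p_right)
    lickport_offset_mm: float = 0.0
    reversal_mode: bool = False
    autoassist_enabled: bool = True
    n_reversals: int = 0

    current_block_type: TrialType = TrialType.LICK_LEFT
    block_corrects: int = 0
    forced_repeat_type: Optional[TrialType] = None
    forced_repeat_corrects_needed: int = 0
    free_reward_pending: Optional[TrialType] = None

    history: deque = field(default_factory=lambda: deque(maxlen=200))
    scored_window: deque = field(default_factory=lambda: deque(maxlen=REVERSAL_WINDOW))
    scored_since_reset: int = 0
    consecutive_errors: dict = field(
        default_factory=lambda: {TrialType.LICK_LEFT: 0, TrialType.LICK_RIGHT: 0}
    )

    def reset_criterion_window(self) -> None:
        self.scored_since_reset = 0
        self.scored_window.clear()


def record_outcome(state: TaskState, trial_type: TrialType, outcome: Outcome) -> TaskState:
    """Fold one finished trial into the controller state."""
    state.history.append((trial_type, outcome))
    if outcome is Outcome.IGNORE:
        # ignores are unscored and break consecutive-error runs
        state.consecutive_errors[trial_type] = 0
        return state

    correct = outcome is Outcome.CORRECT
    state.scored_window.append(1 if correct else 0)
    state.scored_since_reset += 1
    state.consecutive_errors[trial_type] = (
        0 if correct else state.consecutive_errors[trial_type] + 1
    )

    if state.stage is Stage.DIRECTIONAL and trial_type is state.current_block_type:
        if correct:
            state.block_corrects += 1
            if state.block_corrects >= BLOCK_CORRECTS_TO_SWITCH:
                state.current_block_type = (
                    TrialType.LICK_RIGHT
                    if state.current_block_type is TrialType.LICK_LEFT
                    else TrialType.LICK_LEFT
                )
                state.block_corrects = 0

    if state.forced_repeat_type is trial_type and correct:
        state.forced_repeat_corrects_needed -= 1
        if state.forced_repeat_corrects_needed <= 0:
            state.forced_repeat_type = None

    if state.free_reward_pending is trial_type:
        state.free_reward_pending = None
    return state


def _recent_scored(history: Sequence[HistoryEntry], n: int) -> list[HistoryEntry]:
    scored = [(t, o) for t, o in history if o is not Outcome.IGNORE]
    return scored[-n:]


def _perf_by_type(entries: Sequence[HistoryEntry]) -> dict[TrialType, float]:
    out = {}
    for tt in (TrialType.LICK_LEFT, TrialType.LICK_RIGHT):
        sub = [o for t, o in entries if t is tt]
        if sub:
            out[tt] = sum(o is Outcome.CORRECT for o in sub) / len(sub)
    return out


def advance_stage(state: TaskState) -> TaskState:
    """Apply the stage-progression criteria after a scored trial.

    Performance is assessed over consecutive, non-overlapping 30-scored-trial
    blocks: each time a block fills, the criterion is checked once and the
    block resets, whether or not it passed.  (Re-checking a sliding window
    on every trial would let chance streaks trigger advancement long before
    the criterion performance is actually sustained.)
    """
    if state.reversal_mode and state.stage is not Stage.DIRECTIONAL:
        return state  # the 100-trial reversal criterion owns the window
    if state.scored_since_reset < DIRECTIONAL_WINDOW:
        return state
    window = list(state.scored_window)[-DIRECTIONAL_WINDOW:]
    acc = sum(window) / len(window)
    state.reset_criterion_window()

    if state.stage is Stage.DIRECTIONAL and acc >= DIRECTIONAL_CRITERION:
        state.stage = Stage.DISCRIMINATION
    elif state.stage is Stage.DISCRIMINATION and acc >= DISCRIMINATION_CRITERION:
        state.stage = Stage.DELAY
        state.delay_duration = DELAY_START_S
    elif state.stage is Stage.DELAY and acc >= DELAY_CRITERION:
        state.delay_duration = round(state.delay_duration + DELAY_STEP_S, 10)
        if state.delay_duration >= DELAY_FINAL_S:
            state.delay_duration = DELAY_FINAL_S
            state.stage = Stage.COMPLETE
    return state


def select_trial_type(state: TaskState, rng: np.random.Generator) -> TrialType:
    """Draw the next trial type under the stage's scheduling rule."""
    if state.stage is Stage.DIRECTIONAL:
        return state.current_block_type
    if state.forced_repeat_type is not None:
        return state.forced_repeat_type
    p_left = state.trial_type_probabilities[0]
    return TrialType.LICK_LEFT if rng.random() < p_left else TrialType.LICK_RIGHT


def evaluate_autoassist(history: Sequence[HistoryEntry]) -> list[AssistAction]:
    """Evaluate the four auto-assist rules on recent trial history.

    ``history`` is a sequence of (trial_type, outcome) pairs, oldest first,
    including ignore trials.  Each rule stays inactive until its window is
    full.  Returns the list of triggered actions (possibly empty).
    """
    actions: list[AssistAction] = []

    # 1. lickport shift on side bias: >30% gap over 50 trials or >80% over 20
    for window, gap in ((50, BIAS_GAP_50), (20, BIAS_GAP_20)):
        recent = _recent_scored(history, window)
        if len(recent) < window:
            continue
        perf = _perf_by_type(recent)
        if len(perf) == 2:
            left, right = perf[TrialType.LICK_LEFT], perf[TrialType.LICK_RIGHT]
            if abs(left - right) > gap:
                worse = TrialType.LICK_LEFT if left < right else TrialType.LICK_RIGHT
                toward = Spout.LEFT if worse is TrialType.LICK_LEFT else Spout.RIGHT
                actions.append(MoveLickport(toward=toward))
                break

    # 2. free reward after five consecutive errors in one type
    # 4. forced repeat after three consecutive errors in one type
    for tt in (TrialType.LICK_LEFT, TrialType.LICK_RIGHT):
        streak = 0
        for t, o in reversed(history):
            if t is not tt:
                continue
            if o is Outcome.ERROR:
                streak += 1
            else:
                break
        if streak >= FREE_REWARD_ERRORS:
            actions.append(FreeReward(trial_type=tt))
        if streak >= FORCED_REPEAT_ERRORS:
            actions.append(ForcedRepeat(trial_type=tt))

    # 3. present the worse type more frequently (last 30 trials)
    recent = _recent_scored(history, REWEIGHT_WINDOW)
    if len(recent) >= REWEIGHT_WINDOW:
        perf = _perf_by_type(recent)
        if len(perf) == 2:
            left, right = perf[TrialType.LICK_LEFT], perf[TrialType.LICK_RIGHT]
            delta = abs(left - right)
            p_worse = min(0.8, 0.5 + 0.5 * min(0.3, delta))
            if left < right:
                actions.append(Reweight(p_left=p_worse, p_right=1 - p_worse))
            elif right < left:
                actions.append(Reweight(p_left=1 - p_worse, p_right=p_worse))
    return actions


def apply_autoassist(state: TaskState, actions: Sequence[AssistAction]) -> TaskState:
    """Fold assist actions into the controller state."""
    if not state.autoassist_enabled:
        return state
    for a in actions:
        if isinstance(a, Reweight):
            state.trial_type_probabilities = (a.p_left, a.p_right)
        elif isinstance(a, ForcedRepeat):
            if state.forced_repeat_type is None:
                state.forced_repeat_type = a.trial_type
                state.forced_repeat_corrects_needed = FORCED_REPEAT_CORRECTS
        elif isinstance(a, FreeReward):
            state.free_reward_pending = a.trial_type
        elif isinstance(a, MoveLickport):
            step = a.step_mm if a.toward is Spout.LEFT else -a.step_mm
            state.lickport_offset_mm += step
    return state


def check_contingency_reversal(state: TaskState) -> TaskState:
    """Flip the contingency when performance exceeds 80% over 100 trials.

    Active only in reversal mode.  The criterion is strict (81/100 flips,
    80/100 does not) and the window resets after each flip.
    """
    if not state.reversal_mode or state.stage is Stage.DIRECTIONAL:
        return state
    if state.scored_since_reset < REVERSAL_WINDOW:
        return state
    window = list(state.scored_window)[-REVERSAL_WINDOW:]
    passed = sum(window) / len(window) > REVERSAL_CRITERION
    state.reset_criterion_window()  # non-overlapping 100-trial assessments
    if passed:
        state.contingency = (
            Contingency.REVERSED
            if state.contingency is Contingency.STANDARD
            else Contingency.STANDARD
        )
        state.n_reversals += 1
        state.reset_criterion_window()
    return state


def assign_photostim(
    rng: np.random.Generator,
    enabled_epochs: Sequence[StimEpoch],
    intensity_set: Sequence[float],
    probability: float = PHOTOSTIM_PROBABILITY,
) -> Optional[PhotostimAssignment]:
    """Tag a trial for photostimulation with the protocol's probability.

    Epoch and intensity are drawn uniformly from the configured sets.  The
    masking flash is independent of this assignment and covers every trial.
    """
    if len(intensity_set) == 0:
        raise ValueError("intensity_set must not be empty")
    if len(enabled_epochs) == 0:
        raise ValueError("enabled_epochs must not be empty")
    if rng.random() >= probability:
        return None
    epoch = enabled_epochs[int(rng.integers(len(enabled_epochs)))]
    intensity = float(intensity_set[int(rng.integers(len(intensity_set)))])
    return PhotostimAssignment(epoch=StimEpoch(epoch), intensity_mw_mm2=intensity)
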