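"""Closed-loop simulation: protocol state machines driven by the agent.

``run_closed_loop`` executes the full autonomous pipeline for one simulated
mouse: headport-entry luring, head-fixation training, the three task-training
stages (or reversal training) and, optionally, an optogenetic testing phase
with learning frozen.  Time is event-driven: engagement draws space the
fixations, each fixation runs trials until its sampled release, and every
trial goes through the same ``run_trial`` path used for scripted tests.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import headfix_protocol as hf
from . import task_protocol as tp
from .mouse_agent import AgentParams, AgentState, sample_engagement, sample_release_event, sample_trial_behavior, update_learning_state
from .trial_engine import (
    Contingency,
    Outcome,
    Stage,
    StimEpoch,
    TrialConfig,
    TrialRecord,
    TrialType,
    pole_position_for,
    run_trial,
)

__all__ = ["OptoConfig", "RunResult", "run_closed_loop", "make_trained_agent"]

MIN_TRIAL_BUDGET_S = 5.0  # a new trial starts only if this much fixation remains
PERF_TRACK_WINDOW = 200  # scored trials, for the reported learning milestone


@dataclass(frozen=True)
class OptoConfig:
    """Optogenetic testing phase appended after task training."""

    n_trials: int = 1000
    enabled_epochs: tuple = (StimEpoch.SAMPLE, StimEpoch.DELAY, StimEpoch.RESPONSE)
    intensity_set: tuple = (0.3, 1.0, 3.5)  # mW/mm^2, within the 0.3-3.5 range
    region: str = "region"
    probability: float = tp.PHOTOSTIM_PROBABILITY


@dataclass
class RunResult:
    trials: list[TrialRecord]
    fixations: list[hf.FixationEvent]
    headfix: hf.HeadfixState
    task: tp.TaskState
    agent: AgentState
    n_trials: int = 0
    trial_first_70: Optional[int] = None  # first trial with >=70% over last 200 scored
    trial_stage_complete: Optional[int] = None
    n_reversals: int = 0
    wall_time_s: float = 0.0
    stage_trail: list = field(default_factory=list)  # (trial_index, stage value)


def make_trained_agent(params: AgentParams, t: int = 15_000) -> AgentState:
    """Agent jumped to the end of its learning schedule (for testing phases)."""
    state = AgentState(params=params, t=t)
    state.w_stim = state.stim_weight_target(Contingency.STANDARD)
    state.last_choice_coded = 1.0
    state.last_reward_coded = 1.0
    return state


def _trial_config(task: tp.TaskState) -> TrialConfig:
    if task.stage is Stage.DELAY:
        return TrialConfig(delay_duration=task.delay_duration, enforce_delay=True)
    if task.stage is Stage.COMPLETE:
        return TrialConfig(delay_duration=tp.DELAY_FINAL_S, enforce_delay=True)
    return TrialConfig(delay_duration=0.2, enforce_delay=False)


def run_closed_loop(
    seed: Union[int, np.random.Generator],
    agent_params: Optional[AgentParams] = None,
    max_trials: int = 20_000,
    reversal_mode: bool = False,
    stop_after_reversals: Optional[int] = None,
    opto: Optional[OptoConfig] = None,
    start_trained: bool = False,
    keep_trials: bool = True,
) -> RunResult:
    """Simulate one mouse through the autonomous training pipeline.

    Stops when the task stage completes (plus the optional optogenetic
    phase), after ``stop_after_reversals`` contingency flips in reversal
    mode, or at ``max_trials``.  Fully determined by ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = agent_params or AgentParams()

    headfix = hf.HeadfixState()
    task = tp.TaskState(reversal_mode=reversal_mode)
    trials: list[TrialRecord] = []
    fixations: list[hf.FixationEvent] = []
    perf_window: deque = deque(maxlen=PERF_TRACK_WINDOW)
    result = RunResult(trials=trials, fixations=fixations, headfix=headfix,
                       task=task, agent=None)  # agent attached below

    if start_trained:
        agent = make_trained_agent(params)
        headfix.subprotocol = hf.Subprotocol.COMPLETE
        headfix.fixation_duration_s = 31.0
        task.stage = Stage.COMPLETE
        task.delay_duration = tp.DELAY_FINAL_S
    else:
        agent = AgentState(params=params)
    result.agent = agent

    t_wall = 0.0

    # --- headport entry: lure the mouse in, retract the lickport stepwise
    if not start_trained:
        while headfix.subprotocol is hf.Subprotocol.HEADPORT_ENTRY:
            t_wall += float(rng.exponential(30.0))
            if headfix.lickport_distance_mm < hf.LICKPORT_MAX_MM:
                # naive licking: the rewarded spout is hit about half the time
                if rng.random() < 0.5:
                    hf.step_headport_entry(headfix, "rewarded_lick")
            else:
                hf.step_headport_entry(headfix, "switch_trigger")

    # --- head-fixation training: duration ramp 3 -> 30 s
    trial_counter = 0
    last_stage = task.stage

    def _fixation(n_trials_done: int, first_idx, release, rel_time, start, dark):
        fixations.append(
            hf.FixationEvent(
                start_time=start,
                end_time=start + rel_time,
                scheduled_duration=headfix.fixation_duration_s,
                release_type=release,
                thresholds_at_release=headfix.release_thresholds_g,
                n_trials_completed=n_trials_done,
                first_trial_index=first_idx,
                is_dark_cycle=dark,
            )
        )

    while headfix.subprotocol is hf.Subprotocol.HEAD_FIXATION:
        after_error = agent.last_outcome is Outcome.ERROR
        ifi, dark = sample_engagement(agent, rng, after_error=after_error)
        t_wall += ifi
        scheduled = headfix.fixation_duration_s
        release, rel_time = sample_release_event(
            agent, scheduled, headfix.release_thresholds_g, rng
        )
        _fixation(0, None, release, rel_time, t_wall, dark)
        t_wall += rel_time
        hf.step_fixation_training(headfix, release)

    # --- task training (+ optional optogenetic phase)
    opto_active = False
    opto_trials_done = 0
    opto_rng = rng

    def stopping() -> bool:
        if trial_counter >= max_trials:
            return True
        if opto_active:
            return opto_trials_done >= opto.n_trials
        if reversal_mode:
            if stop_after_reversals is not None:
                return task.n_reversals >= stop_after_reversals
            return False
        # protocol completion and criterion performance are distinct events:
        # the delay ramp can finish while performance is still climbing, so
        # testing continues until >=70% correct is sustained as well
        return (task.stage is Stage.COMPLETE and opto is None
                and result.trial_first_70 is not None)

    def maybe_enter_opto():
        nonlocal opto_active
        if opto is not None and not opto_active and task.stage is Stage.COMPLETE:
            opto_active = True
            agent.frozen = True
            task.autoassist_enabled = False
            headfix.extend_cap()

    maybe_enter_opto()
    while not stopping():
        after_error = agent.last_outcome is Outcome.ERROR
        ifi, dark = sample_engagement(agent, rng, after_error=after_error)
        t_wall += ifi
        scheduled = headfix.fixation_duration_s
        release, rel_time = sample_release_event(
            agent, scheduled, headfix.release_thresholds_g, rng
        )
        fix_start = t_wall
        first_idx = None
        n_done = 0
        elapsed = 0.0
        while rel_time - elapsed >= MIN_TRIAL_BUDGET_S and not stopping():
            trial_type = tp.select_trial_type(task, rng)
            config = _trial_config(task)

            stim = None
            effect = None
            if opto_active:
                stim = tp.assign_photostim(
                    opto_rng, opto.enabled_epochs, opto.intensity_set,
                    probability=opto.probability,
                )
                if stim is not None:
                    effect = params.photostim_effects.get(
                        (opto.region, stim.epoch.value)
                    )

            assist_logit = 0.0
            assist_flags = set()
            if task.free_reward_pending is trial_type:
                side = 1.0 if trial_type is TrialType.LICK_LEFT else -1.0
                correct_sign = side  # trial type names the rewarded direction
                assist_logit = 3.0 * correct_sign
                assist_flags.add("free_reward")
            if task.forced_repeat_type is trial_type:
                assist_flags.add("forced_repeat")

            pole = pole_position_for(trial_type, task.contingency)
            plan = sample_trial_behavior(
                agent, pole, task.stage, config.delay_duration, rng,
                stim_effect=effect, assist_logit=assist_logit,
            )
            record = run_trial(
                config, plan, trial_type,
                stage=task.stage if task.stage is not Stage.COMPLETE else Stage.DELAY,
                contingency=task.contingency, stim=stim,
                trial_index=trial_counter,
            )
            record.autoassist_flags |= assist_flags
            if first_idx is None:
                first_idx = trial_counter
            trial_counter += 1
            n_done += 1
            opto_trials_done += 1 if opto_active else 0
            elapsed += record.timeline.trial_end
            if keep_trials:
                trials.append(record)

            tp.record_outcome(task, trial_type, record.outcome)
            if task.autoassist_enabled and task.stage in (Stage.DISCRIMINATION, Stage.DELAY):
                tp.apply_autoassist(task, tp.evaluate_autoassist(task.history))
            if not opto_active:
                tp.advance_stage(task)
                tp.check_contingency_reversal(task)
            update_learning_state(agent, record)

            if record.outcome is not Outcome.IGNORE:
                perf_window.append(1 if record.outcome is Outcome.CORRECT else 0)
                if (
                    result.trial_first_70 is None
                    and task.stage is not Stage.DIRECTIONAL
                    and len(perf_window) == PERF_TRACK_WINDOW
                    and sum(perf_window) / PERF_TRACK_WINDOW >= 0.70
                ):
                    result.trial_first_70 = trial_counter
            if task.stage is not last_stage:
                result.stage_trail.append((trial_counter, task.stage.value))
                last_stage = task.stage
                if task.stage is Stage.COMPLETE:
                    result.trial_stage_complete = trial_counter
                    headfix.extend_cap()
                maybe_enter_opto()
        # a running trial may finish just past the scheduled release
        actual = max(rel_time, elapsed) if n_done else rel_time
        _fixation(n_done, first_idx, release, actual, fix_start, dark)
        t_wall += actual
        if release is hf.ReleaseType.TIME_UP and headfix.subprotocol is hf.Subprotocol.HEAD_FIXATION:
            hf.step_fixation_training(headfix, release)

    result.n_trials = trial_counter
    result.n_reversals = task.n_reversals
    result.wall_time_s = t_wall
    return result
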