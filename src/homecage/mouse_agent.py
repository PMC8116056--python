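"""Generative simulated mouse for closed-loop protocol testing.

The agent closes the loop with the protocol state machines and doubles as
the repository's synthetic-data generator.  None of its parameters are
estimates of real mice; they are artifact choices that reproduce the
qualitative structure of home-cage training data:

* **Choice policy** — a logistic policy on +/-1-coded inputs,
  ``P(left) = sigma(w_stim*S0 + w_choice_history*A1 + w_wsls*A1*R1 + bias)``,
  with a lapse rate mixing in uniform choices.  Early in training the policy
  leans on its own recent choices and their outcomes — a win-stay-lose-switch
  strategy, which is what lets block-structured directional training work:
  after a block switch, repeated unrewarded licks push the agent to the
  other spout.  With training the stimulus weight grows while the history
  and WSLS weights shrink.
* **Learning** — the stimulus weight follows a delta rule toward a
  sigmoid-scheduled asymptote whose sign tracks the current contingency, so
  the same mechanism produces the slow initial acquisition and the faster
  re-learning after a contingency reversal.  The history weight follows a
  matching non-increasing sigmoid schedule.  Schedules freeze during
  optogenetic testing.
* **Engagement** — inter-fixation intervals are a two-component mixture
  (short within-bout gaps, long between-bout gaps), multiplied by a constant
  factor after error-ending fixations; a fixed fraction of fixations falls
  in the dark cycle.
* **Struggling** — threshold-crossing load excursions arrive as a Poisson
  process whose effective rate falls off exponentially with the margin
  between the resting load and the nearer release threshold, so widening the
  thresholds genuinely reduces self-releases.
* **Photostimulation** — per (region, epoch) effects modify the policy on
  stimulated trials only: an additive bias toward one side and/or a
  multiplicative attenuation of the stimulus weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .trial_engine import (
    Choice,
    Contingency,
    LickPlan,
    Outcome,
    PolePosition,
    Spout,
    Stage,
    TrialRecord,
    TrialType,
)

__all__ = [
    "AgentParams",
    "AgentState",
    "PhotostimEffect",
    "sigmoid",
    "sample_trial_behavior",
    "sample_engagement",
    "sample_release_event",
    "update_learning_state",
    "generate_policy_trials",
    "generate_opto_dataset",
    "generate_load_stream",
]


def sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


@dataclass(frozen=True)
class PhotostimEffect:
    """Policy modification applied on photostimulated trials.

    ``bias_shift`` adds to the logit toward lick-left (+) or lick-right (-);
    ``stim_weight_scale`` multiplies the learned stimulus weight (0 wipes out
    the stimulus, 1 leaves it intact).
    """

    bias_shift: float = 0.0
    stim_weight_scale: float = 1.0


@dataclass(frozen=True)
class AgentParams:
    """Tunable agent parameters (see module docstring for semantics)."""

    # choice policy / learning schedule (units: logits, trials)
    w_stim_max: float = 3.0
    w_choice_history_init: float = 1.5
    w_choice_history_final: float = 0.2
    w_wsls_init: float = 2.5
    w_wsls_final: float = 0.3
    bias: float = 0.0
    learning_midpoint_trials: float = 6000.0
    learning_scale_trials: float = 1000.0
    assoc_learning_rate: float = 0.02  # per scored trial
    lapse_rate: float = 0.05
    ignore_rate: float = 0.02
    # early licks (per-trial Poisson rate, exponential decay with training)
    early_lick_rate_init: float = 0.3
    early_lick_decay_trials: float = 3000.0
    # engagement
    p_within_bout: float = 0.85
    within_bout_scale_s: float = 1.0
    between_bout_scale_s: float = 1800.0
    error_ifi_multiplier: float = 1.5
    dark_cycle_preference: float = 0.67
    # struggling / escapes
    struggle_rate_hz: float = 0.02
    struggle_scale_g: float = 15.0
    resting_load_g: float = 10.0
    escape_prob: float = 0.05
    body_weight_g: float = 25.0
    # photostim effects, keyed by (region_label, epoch)
    photostim_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("lapse_rate", "ignore_rate", "escape_prob", "dark_cycle_preference"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.error_ifi_multiplier < 1.0:
            raise ValueError("error_ifi_multiplier must be >= 1")


@dataclass
class AgentState:
    """Mutable agent state: trial clock, learned weights, last choice."""

    params: AgentParams
    t: int = 0  # scored trials experienced
    w_stim: float = 0.0  # signed: positive under standard contingency
    last_choice_coded: float = 0.0  # +1 left, -1 right, 0 before first choice
    last_reward_coded: float = 0.0  # +1 rewarded, -1 not, 0 before first choice
    last_outcome: Optional[Outcome] = None
    frozen: bool = False  # learning frozen during optogenetic testing

    def _decaying(self, init: float, final: float) -> float:
        p = self.params
        s = sigmoid((self.t - p.learning_midpoint_trials) / p.learning_scale_trials)
        return init - (init - final) * s

    @property
    def w_choice_history(self) -> float:
        p = self.params
        return self._decaying(p.w_choice_history_init, p.w_choice_history_final)

    @property
    def w_wsls(self) -> float:
        p = self.params
        return self._decaying(p.w_wsls_init, p.w_wsls_final)

    def stim_weight_target(self, contingency: Contingency) -> float:
        p = self.params
        g = p.w_stim_max * sigmoid((self.t - p.learning_midpoint_trials) / p.learning_scale_trials)
        return g if contingency is Contingency.STANDARD else -g

    def early_lick_rate(self) -> float:
        p = self.params
        return p.early_lick_rate_init * math.exp(-self.t / p.early_lick_decay_trials)


def _stim_coded(pole: PolePosition) -> float:
    # anterior pole instructs lick-left under the standard contingency
    return 1.0 if pole is PolePosition.ANTERIOR else -1.0


def sample_trial_behavior(
    state: AgentState,
    pole_position: PolePosition,
    stage: Stage,
    delay_duration: float,
    rng: np.random.Generator,
    stim_effect: Optional[PhotostimEffect] = None,
    assist_logit: float = 0.0,
) -> LickPlan:
    """Sample one trial's lick plan from the current policy.

    The logit is ``w_stim*S0 + w_choice_history*A1 + w_wsls*A1*R1 + bias``
    (plus the photostimulation modification on stimulated trials, plus
    ``assist_logit`` toward lick-left when a free-reward assist just primed
    a spout); with probability ``lapse_rate`` the choice is uniform, and
    with ``ignore_rate`` the agent does not respond at all.  Early licks are
    emitted in the sample/delay epochs at a rate that decays with training.
    """
    p = state.params
    s0 = _stim_coded(pole_position)
    w_stim = state.w_stim
    extra_bias = 0.0
    if stim_effect is not None:
        w_stim = w_stim * stim_effect.stim_weight_scale
        extra_bias = stim_effect.bias_shift
    z = (
        w_stim * s0
        + state.w_choice_history * state.last_choice_coded
        + state.w_wsls * state.last_choice_coded * state.last_reward_coded
        + p.bias
        + extra_bias
        + assist_logit
    )

    early: list[tuple[float, Spout]] = []
    rate = state.early_lick_rate()
    if rate > 0:
        n_early = rng.poisson(rate)
        pre_go = 1.3 + delay_duration
        for _ in range(int(n_early)):
            t = float(rng.uniform(0.0, pre_go))
            spout = Spout.LEFT if rng.random() < 0.5 else Spout.RIGHT
            early.append((t, spout))
        early.sort(key=lambda e: e[0])

    if rng.random() < p.ignore_rate:
        return LickPlan(early_licks=tuple(early), response=None)

    if rng.random() < p.lapse_rate:
        go_left = rng.random() < 0.5
    else:
        go_left = rng.random() < sigmoid(z)
    latency = 0.1 + float(rng.exponential(0.15))
    latency = min(latency, 1.4)
    spout = Spout.LEFT if go_left else Spout.RIGHT
    return LickPlan(early_licks=tuple(early), response=(latency, spout))


def update_learning_state(state: AgentState, trial: TrialRecord) -> AgentState:
    """Advance the learning schedules by one trial.

    The stimulus weight moves toward its scheduled, contingency-signed
    asymptote by a delta rule; the trial clock advances on scored trials.
    Frozen agents (optogenetic testing) keep their weights.
    """
    if trial.choice is not Choice.IGNORE:
        state.last_choice_coded = 1.0 if trial.choice is Choice.LEFT else -1.0
        state.last_reward_coded = 1.0 if trial.rewarded else -1.0
        state.last_outcome = trial.outcome
        if not state.frozen:
            state.t += 1
            target = state.stim_weight_target(trial.contingency)
            state.w_stim += state.params.assoc_learning_rate * (target - state.w_stim)
    return state


def sample_engagement(
    state: AgentState,
    rng: np.random.Generator,
    after_error: bool = False,
) -> tuple[float, bool]:
    """Sample the interval to the next head-fixation.

    Returns ``(ifi_seconds, is_dark_cycle)``.  The IFI is a mixture of a
    short within-bout exponential and a long between-bout exponential; the
    whole draw is scaled by ``error_ifi_multiplier`` when the previous
    fixation ended on an error trial, so the mean ratio equals the
    multiplier exactly.
    """
    p = state.params
    if rng.random() < p.p_within_bout:
        ifi = float(rng.exponential(p.within_bout_scale_s))
    else:
        ifi = float(rng.exponential(p.between_bout_scale_s))
    if after_error:
        ifi *= p.error_ifi_multiplier
    is_dark = rng.random() < p.dark_cycle_preference
    return ifi, is_dark


def sample_release_event(
    state: AgentState,
    scheduled_duration: float,
    thresholds: tuple[float, float],
    rng: np.random.Generator,
):
    """Sample how a fixation ends, given the current release thresholds.

    Escapes occur with a fixed probability within the 0.2 s clamp window.
    Struggle excursions arrive at ``struggle_rate_hz``; an excursion crosses
    a threshold with probability ``exp(-margin / struggle_scale_g)`` where
    margin is the distance from the resting load to the nearer threshold, so
    the effective self-release hazard is a thinned Poisson rate.  Returns
    ``(release_type, time)`` with time in seconds from clamp onset.
    """
    from .headfix_protocol import ReleaseType

    p = state.params
    if rng.random() < p.escape_prob:
        return ReleaseType.ESCAPE, float(rng.uniform(0.0, 0.2))
    lower, upper = thresholds
    margin = min(p.resting_load_g - lower, upper - p.resting_load_g)
    p_cross = math.exp(-max(margin, 0.0) / p.struggle_scale_g) if margin > 0 else 1.0
    rate = p.struggle_rate_hz * p_cross
    if rate > 0:
        t_self = float(rng.exponential(1.0 / rate))
        if t_self < scheduled_duration:
            return ReleaseType.SELF_RELEASE, t_self
    return ReleaseType.TIME_UP, scheduled_duration


# ---------------------------------------------------------------------------
# stand-alone synthetic-data generators


def generate_policy_trials(
    n_trials: int,
    w_stim: float,
    w_choice_history: float,
    bias: float,
    rng: np.random.Generator,
    lapse_rate: float = 0.0,
    contingency: Contingency = Contingency.STANDARD,
) -> list[TrialRecord]:
    """Trials from a static logistic policy on random +/-1 stimuli.

    Minimal records (no lick timing) for the choice-model analyses and the
    parameter-recovery suite.  The policy is the reduced strategy model:
    logit = w_stim * S0 + w_choice_history * A1 + bias.
    """
    trials: list[TrialRecord] = []
    a_prev = 1.0 if rng.random() < 0.5 else -1.0
    for i in range(n_trials):
        s = 1.0 if rng.random() < 0.5 else -1.0
        pole = PolePosition.ANTERIOR if s > 0 else PolePosition.POSTERIOR
        if contingency is Contingency.STANDARD:
            ttype = TrialType.LICK_LEFT if s > 0 else TrialType.LICK_RIGHT
        else:
            ttype = TrialType.LICK_RIGHT if s > 0 else TrialType.LICK_LEFT
        z = w_stim * s + w_choice_history * a_prev + bias
        if lapse_rate > 0 and rng.random() < lapse_rate:
            left = rng.random() < 0.5
        else:
            left = rng.random() < sigmoid(z)
        choice = Choice.LEFT if left else Choice.RIGHT
        correct = (choice is Choice.LEFT) == (ttype is TrialType.LICK_LEFT)
        trials.append(
            TrialRecord(
                trial_index=i,
                trial_type=ttype,
                pole_position=pole,
                contingency=contingency,
                stage=Stage.DISCRIMINATION,
                delay_duration=0.2,
                lick_events=[],
                choice=choice,
                outcome=Outcome.CORRECT if correct else Outcome.ERROR,
                rewarded=correct,
            )
        )
        a_prev = 1.0 if left else -1.0
    return trials


def generate_opto_dataset(
    n_mice: int,
    n_sessions: int,
    trials_per_session: int,
    p_correct_control: float,
    stim_effect_points: float,
    rng: np.random.Generator,
    stim_fraction: float = 0.10,
    mouse_sd: float = 0.0,
) -> pd.DataFrame:
    """Hierarchical trial table for photostimulation effect analyses.

    Each session holds ``trials_per_session`` trials, a random 10% of which
    are photostimulated; stimulated trials are correct with probability
    ``p_correct_control + stim_effect_points / 100``.  ``mouse_sd`` adds a
    per-mouse offset to the control accuracy (clipped to [0.05, 0.95]).
    Columns: mouse, session, condition ('control'/'photostim'), outcome.
    """
    rows = []
    for m in range(n_mice):
        p_m = p_correct_control + (rng.normal(0.0, mouse_sd) if mouse_sd > 0 else 0.0)
        p_m = min(max(p_m, 0.05), 0.95)
        p_stim = min(max(p_m + stim_effect_points / 100.0, 0.01), 0.99)
        for s in range(n_sessions):
            is_stim = rng.random(trials_per_session) < stim_fraction
            p_vec = np.where(is_stim, p_stim, p_m)
            correct = rng.random(trials_per_session) < p_vec
            for stim, corr in zip(is_stim, correct):
                rows.append(
                    (
                        f"mouse{m}",
                        s,
                        "photostim" if stim else "control",
                        "correct" if corr else "error",
                    )
                )
    return pd.DataFrame(rows, columns=["mouse", "session", "condition", "outcome"])


def generate_load_stream(
    duration_s: float,
    rng: np.random.Generator,
    body_weight_g: float = 25.0,
    occupancy: float = 0.3,
    noise_g: float = 0.1,
    partial_step_fraction: float = 0.05,
    sample_hz: float = 20.0,
):
    """Load-cell samples emulating a mouse intermittently on the platform.

    On-platform samples read ~N(body_weight, noise^2); a small fraction are
    transient partial steps at ~40% of body weight; off-platform samples
    read ~0.  Returns a list of LoadSample.
    """
    from .headfix_protocol import LoadSample

    n = int(duration_s * sample_hz)
    t = np.arange(n) / sample_hz
    on = rng.random(n) < occupancy
    w = rng.normal(0.0, 0.02, size=n)
    onw = rng.normal(body_weight_g, noise_g, size=n)
    partial = rng.random(n) < partial_step_fraction
    onw = np.where(partial, rng.normal(0.4 * body_weight_g, 1.0, size=n), onw)
    w = np.where(on, onw, w)
    return [LoadSample(time=float(ti), weight_g=float(wi)) for ti, wi in zip(t, w)]
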