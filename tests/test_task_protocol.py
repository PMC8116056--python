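"""Stage progression, trial scheduling, auto-assists, reversal, photostim."""

import numpy as np
import pytest

from homecage.task_protocol import (
    ForcedRepeat,
    FreeReward,
    MoveLickport,
    Reweight,
    TaskState,
    advance_stage,
    apply_autoassist,
    assign_photostim,
    check_contingency_reversal,
    evaluate_autoassist,
    record_outcome,
    select_trial_type,
)
from homecage.trial_engine import Contingency, Outcome, Spout, Stage, StimEpoch, TrialType

L, R = TrialType.LICK_LEFT, TrialType.LICK_RIGHT
C, E, I = Outcome.CORRECT, Outcome.ERROR, Outcome.IGNORE


def feed(state, outcomes, trial_type=L, advance=False):
    for o in outcomes:
        record_outcome(state, trial_type, o)
        if advance:
            advance_stage(state)
    return state


class TestAdvanceStage:
    def test_directional_advances_at_70pct_over_30(self):
        s = TaskState()
        feed(s, [C] * 22 + [E] * 8)
        advance_stage(s)
        assert s.stage is Stage.DISCRIMINATION

    def test_directional_holds_below_70pct(self):
        s = TaskState()
        feed(s, [C] * 20 + [E] * 10)  # 66.7%
        advance_stage(s)
        assert s.stage is Stage.DIRECTIONAL

    def test_discrimination_holds_at_74pct(self):
        s = TaskState(stage=Stage.DISCRIMINATION)
        feed(s, [C] * 22 + [E] * 8)  # 73.3% < 75%
        advance_stage(s)
        assert s.stage is Stage.DISCRIMINATION

    def test_delay_ramp_five_passes_to_complete(self):
        """Delay schedule oracle: (1.3 - 0.3)/0.2 = 5 criterion passes."""
        s = TaskState(stage=Stage.DELAY, delay_duration=0.3)
        passes = 0
        while s.stage is Stage.DELAY:
            feed(s, [C] * 30)
            advance_stage(s)
            passes += 1
        assert passes == 5
        assert s.delay_duration == pytest.approx(1.3)
        assert s.stage is Stage.COMPLETE

    def test_ignores_excluded_from_criterion(self):
        s = TaskState()
        feed(s, ([C] * 2 + [I]) * 15)  # 30 corrects among 45 trials
        advance_stage(s)
        assert s.stage is Stage.DISCRIMINATION

    def test_no_partial_window_trigger(self):
        s = TaskState()
        feed(s, [C] * 29)
        advance_stage(s)
        assert s.stage is Stage.DIRECTIONAL

    def test_stage_never_regresses(self, rng):
        s = TaskState()
        order = [Stage.DIRECTIONAL, Stage.DISCRIMINATION, Stage.DELAY, Stage.COMPLETE]
        prev = 0
        for _ in range(3000):
            o = C if rng.random() < 0.8 else E
            record_outcome(s, L if rng.random() < 0.5 else R, o)
            advance_stage(s)
            assert order.index(s.stage) >= prev
            prev = order.index(s.stage)


class TestSelectTrialType:
    def test_directional_block_switches_after_three_correct(self, rng):
        s = TaskState()
        assert select_trial_type(s, rng) is L
        feed(s, [C, E, C, C], trial_type=L)
        assert select_trial_type(s, rng) is R

    def test_forced_repeat_overrides_draw(self, rng):
        s = TaskState(stage=Stage.DISCRIMINATION, forced_repeat_type=R,
                      forced_repeat_corrects_needed=2)
        assert all(select_trial_type(s, rng) is R for _ in range(20))
        feed(s, [C, C], trial_type=R)
        assert s.forced_repeat_type is None

    def test_equal_probabilities_are_balanced(self):
        s = TaskState(stage=Stage.DISCRIMINATION)
        rng = np.random.default_rng(12)
        n = 10_000
        left = sum(select_trial_type(s, rng) is L for _ in range(n))
        # binomial 99% CI around 0.5
        assert abs(left / n - 0.5) < 2.58 * 0.5 / np.sqrt(n)

    def test_forced_repeat_exits_for_any_accuracy(self):
        """No deadlock: even a poor agent escapes a forced-repeat episode."""
        rng = np.random.default_rng(3)
        lengths = []
        for _ in range(200):
            s = TaskState(stage=Stage.DISCRIMINATION, forced_repeat_type=R,
                          forced_repeat_corrects_needed=2)
            n = 0
            while s.forced_repeat_type is not None:
                record_outcome(s, R, C if rng.random() < 0.2 else E)
                n += 1
            lengths.append(n)
        assert np.mean(lengths) < 50  # ~2/0.2 = 10 expected


class TestAutoassist:
    @staticmethod
    def _biased_history(n_left, left_acc, n_right, right_acc, rng):
        hist = []
        for tt, n, acc in ((L, n_left, left_acc), (R, n_right, right_acc)):
            k = int(round(n * acc))
            hist += [(tt, C)] * k + [(tt, E)] * (n - k)
        rng.shuffle(hist)
        return hist

    def test_bias_over_50_trials_moves_lickport(self, rng):
        hist = self._biased_history(25, 0.9, 25, 0.55, rng)
        actions = evaluate_autoassist(hist)
        moves = [a for a in actions if isinstance(a, MoveLickport)]
        assert moves and moves[0].toward is Spout.RIGHT

    def test_five_consecutive_errors_trigger_free_reward(self):
        hist = [(L, C), (R, C)] * 25 + [(L, E)] * 5
        actions = evaluate_autoassist(hist)
        assert FreeReward(trial_type=L) in actions
        assert ForcedRepeat(trial_type=L) in actions

    def test_ignore_breaks_error_run(self):
        hist = [(L, C), (R, C)] * 25 + [(L, E), (L, E), (L, I), (L, E), (L, E)]
        actions = evaluate_autoassist(hist)
        assert not any(isinstance(a, (FreeReward, ForcedRepeat)) for a in actions)

    def test_balanced_performance_no_bias_actions(self, rng):
        hist = self._biased_history(25, 0.8, 25, 0.8, rng)
        actions = evaluate_autoassist(hist)
        assert not any(isinstance(a, (MoveLickport, FreeReward, ForcedRepeat))
                       for a in actions)

    def test_reweight_favors_worse_type(self, rng):
        hist = self._biased_history(15, 1.0, 15, 0.6, rng)
        actions = evaluate_autoassist(hist)
        rw = [a for a in actions if isinstance(a, Reweight)]
        assert rw and rw[0].p_right > 0.5
        # p(worse) = 0.5 + 0.5*min(0.3, 0.4)
        assert rw[0].p_right == pytest.approx(0.65)

    def test_rules_inactive_before_window_fills(self):
        actions = evaluate_autoassist([(L, E)] * 10)
        assert not any(isinstance(a, (MoveLickport, Reweight)) for a in actions)

    def test_apply_respects_disable_flag(self):
        s = TaskState(autoassist_enabled=False)
        apply_autoassist(s, [Reweight(p_left=0.65, p_right=0.35)])
        assert s.trial_type_probabilities == (0.5, 0.5)


class TestContingencyReversal:
    def _state(self):
        return TaskState(stage=Stage.DISCRIMINATION, reversal_mode=True)

    def test_85_of_100_flips(self):
        s = self._state()
        feed(s, [C] * 85 + [E] * 15)
        check_contingency_reversal(s)
        assert s.contingency is Contingency.REVERSED
        assert s.n_reversals == 1

    def test_exactly_80_does_not_flip(self):
        s = self._state()
        feed(s, [C] * 80 + [E] * 20)
        check_contingency_reversal(s)
        assert s.contingency is Contingency.STANDARD

    def test_double_flip_returns_to_standard(self):
        s = self._state()
        for _ in range(2):
            feed(s, [C] * 90 + [E] * 10)
            check_contingency_reversal(s)
        assert s.n_reversals == 2
        assert s.contingency is Contingency.STANDARD

    def test_inactive_outside_reversal_mode(self):
        s = TaskState(stage=Stage.DISCRIMINATION, reversal_mode=False)
        feed(s, [C] * 100)
        check_contingency_reversal(s)
        assert s.contingency is Contingency.STANDARD


class TestAssignPhotostim:
    def test_stim_fraction_near_10pct(self):
        rng = np.random.default_rng(5)
        n = 10_000
        hits = sum(
            assign_photostim(rng, [StimEpoch.DELAY], [1.0]) is not None
            for _ in range(n)
        )
        p = hits / n
        assert abs(p - 0.10) < 2.58 * np.sqrt(0.1 * 0.9 / n)

    def test_epochs_restricted_to_enabled(self, rng):
        for _ in range(200):
            a = assign_photostim(rng, [StimEpoch.DELAY], [1.0, 2.0], probability=1.0)
            assert a.epoch is StimEpoch.DELAY
            assert a.intensity_mw_mm2 in (1.0, 2.0)

    def test_zero_probability_never_assigns(self, rng):
        assert all(
            assign_photostim(rng, [StimEpoch.SAMPLE], [1.0], probability=0.0) is None
            for _ in range(100)
        )

    def test_empty_intensity_set_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_photostim(rng, [StimEpoch.SAMPLE], [])
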