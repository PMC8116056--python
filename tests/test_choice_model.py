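"""Choice-strategy model: design coding, MLE, guarded CV, bootstrap tests."""

import numpy as np
import pytest

from homecage.choice_model import (
    REGRESSOR_NAMES,
    ChoiceDesign,
    build_design,
    crossval_predict,
    cv_blocks,
    fit_logistic,
    partial_model_pvalue,
    penalized_loglik,
    predict_left,
    regressor_reliance,
    shuffle_control,
    sliding_window_analysis,
)
from homecage.mouse_agent import generate_policy_trials, sigmoid
from homecage.trial_engine import Choice, TrialType

from conftest import make_trial

L, R = TrialType.LICK_LEFT, TrialType.LICK_RIGHT


def scripted_design(pairs):
    """Design from (trial_type, choice) pairs."""
    trials = [make_trial(i, tt, ch) for i, (tt, ch) in enumerate(pairs)]
    return build_design(trials), trials


class TestBuildDesign:
    def test_wsls_is_previous_choice_times_reward(self):
        # 20 history trials, then: previous trial chose left and was rewarded
        pairs = [(L, Choice.LEFT)] * 21 + [(R, Choice.RIGHT)]
        design, _ = scripted_design(pairs)
        row = design.X[-1]
        cols = design.columns
        assert row[cols.index("A1")] == 1.0
        assert row[cols.index("R1")] == 1.0
        assert row[cols.index("WSLS")] == 1.0

    def test_wsls_negative_after_unrewarded_choice(self):
        pairs = [(L, Choice.LEFT)] * 21 + [(R, Choice.LEFT)] + [(R, Choice.RIGHT)]
        design, _ = scripted_design(pairs)
        row = design.X[-1]  # previous trial: chose left on a lick-right trial
        cols = design.columns
        assert row[cols.index("A1")] == 1.0
        assert row[cols.index("R1")] == -1.0
        assert row[cols.index("WSLS")] == -1.0

    def test_savg_extreme_when_history_one_sided(self):
        pairs = [(R, Choice.RIGHT)] * 20 + [(L, Choice.LEFT)]
        design, _ = scripted_design(pairs)
        assert design.X[-1][design.columns.index("Savg")] == -1.0

    def test_rows_require_20_scored_predecessors(self):
        design, _ = scripted_design([(L, Choice.LEFT)] * 20)
        assert len(design) == 0
        design, _ = scripted_design([(L, Choice.LEFT)] * 25)
        assert len(design) == 5

    def test_ignores_dropped_but_history_spans_them(self):
        pairs = [(L, Choice.LEFT)] * 21 + [(R, Choice.IGNORE), (R, Choice.RIGHT)]
        design, _ = scripted_design(pairs)
        assert len(design) == 2  # the ignore trial contributes no row
        # history for the last row comes from the last scored trial
        assert design.X[-1][design.columns.index("A1")] == 1.0


class TestFitLogistic:
    def test_null_data_gives_small_weights_and_chance_cv(self):
        rng = np.random.default_rng(10)
        X = rng.choice([-1.0, 1.0], size=(2000, len(REGRESSOR_NAMES)))
        y = rng.integers(0, 2, size=2000)
        design = ChoiceDesign(X=X, y=y, columns=list(REGRESSOR_NAMES),
                              trial_indices=np.arange(2000))
        fit = fit_logistic(design)
        assert np.all(np.abs(fit.beta) < 0.15)
        acc = crossval_predict(design)
        assert abs(acc - 0.5) < 0.05

    def test_separable_stimulus_predicts_perfectly(self):
        rng = np.random.default_rng(11)
        X = rng.choice([-1.0, 1.0], size=(200, 2))
        y = (X[:, 0] > 0).astype(int)
        design = ChoiceDesign(X=X, y=y, columns=["S0", "A1"],
                              trial_indices=np.arange(200))
        fit = fit_logistic(design)
        assert np.array_equal(predict_left(X, fit), y)

    def test_one_class_response_flagged(self):
        X = np.ones((30, 2))
        design = ChoiceDesign(X=X, y=np.ones(30, dtype=int), columns=["S0", "A1"],
                              trial_indices=np.arange(30))
        with pytest.warns(UserWarning):
            fit = fit_logistic(design)
        assert fit.saturated
        assert np.all(predict_left(X, fit) == 1)

    def test_matches_grid_search_oracle_on_small_instances(self):
        """MLE equals an independent grid maximizer of the penalized
        likelihood on 20-trial, 2-regressor instances."""
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 5:
            X = rng.choice([-1.0, 1.0], size=(20, 2))
            z = 1.2 * X[:, 0] - 0.4 * X[:, 1] + 0.2
            y = (rng.random(20) < 1 / (1 + np.exp(-z))).astype(int)
            if len(np.unique(y)) < 2:
                continue
            design = ChoiceDesign(X=X, y=y, columns=["S0", "A1"],
                                  trial_indices=np.arange(20))
            fit = fit_logistic(design)
            if np.max(np.abs(fit.beta)) > 3 or abs(fit.intercept) > 3:
                continue  # near-separable: grid oracle domain excluded
            oracle = _grid_maximizer(X, y)
            mle = np.array([fit.beta[0], fit.beta[1], fit.intercept])
            assert np.max(np.abs(mle - oracle)) < 1e-2
            # and the fitted likelihood is at least the oracle's
            assert penalized_loglik(X, y, fit.beta, fit.intercept) >= \
                penalized_loglik(X, y, oracle[:2], oracle[2]) - 1e-9
            checked += 1


def _grid_maximizer(X, y, ridge=1e-4):
    """Iteratively refined dense grid search over (b1, b2, intercept)."""
    center = np.zeros(3)
    width = 4.0
    for _ in range(4):
        grids = [np.linspace(c - width, c + width, 41) for c in center]
        B = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
        Z = X @ B[:, :2].T + B[:, 2]
        ll = (y[:, None] * Z - np.logaddexp(0, Z)).sum(axis=0)
        ll -= ridge * (B[:, 0] ** 2 + B[:, 1] ** 2)
        center = B[np.argmax(ll)]
        width /= 10
    return center


class TestCrossValidation:
    @pytest.mark.parametrize("n_rows", [200, 480])
    def test_guard_zones_hold_exhaustively(self, n_rows):
        """No training trial lies within 20 trials of any test trial."""
        for test, train in cv_blocks(n_rows):
            dmin = np.min(np.abs(test[:, None] - train[None, :]))
            assert dmin > 20

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            cv_blocks(80)

    def test_cv_accuracy_tracks_policy_closed_form(self):
        rng = np.random.default_rng(13)
        trials = generate_policy_trials(520, 3.0, 0.0, 0.0, rng)
        acc = crossval_predict(build_design(trials))
        assert abs(acc - sigmoid(3.0)) < 0.03

    def test_shuffled_responses_drop_to_chance(self):
        rng = np.random.default_rng(14)
        trials = generate_policy_trials(520, 3.0, 0.0, 0.0, rng)
        design = shuffle_control(build_design(trials), rng)
        assert abs(crossval_predict(design) - 0.5) < 0.06


class TestPartialModel:
    def test_zero_column_forces_degenerate_strict_p(self):
        rng = np.random.default_rng(15)
        trials = generate_policy_trials(520, 2.0, 0.0, 0.0, rng)
        design = build_design(trials)
        design.X[:, design.columns.index("A3")] = 0.0
        res = partial_model_pvalue(design, "A3", n_boot=500, rng=rng)
        assert res.p_strict == 0.0
        assert res.tie_fraction == 1.0
        assert res.p_mid == 0.5

    def test_informative_regressor_detected(self):
        rng = np.random.default_rng(16)
        trials = generate_policy_trials(520, 3.0, 0.0, 0.0, rng)
        res = partial_model_pvalue(build_design(trials), "S0", n_boot=1000, rng=rng)
        assert res.p_strict < 0.05
        assert res.full_accuracy > res.partial_accuracy


class TestSlidingWindows:
    def test_window_count_arithmetic(self, rng):
        trials = generate_policy_trials(1000, 2.0, 0.5, 0.0, rng)
        fits = sliding_window_analysis(trials)
        assert len(fits) == 6
        assert [f.window_start for f in fits] == [1, 101, 201, 301, 401, 501]

    def test_exactly_one_window_at_500(self, rng):
        trials = generate_policy_trials(500, 2.0, 0.5, 0.0, rng)
        assert len(sliding_window_analysis(trials)) == 1

    def test_short_input_warns_and_returns_empty(self, rng):
        trials = generate_policy_trials(300, 2.0, 0.5, 0.0, rng)
        with pytest.warns(UserWarning):
            assert sliding_window_analysis(trials) == []


class TestRelianceAndShuffle:
    def test_five_consecutive_significant_windows(self):
        series = [{"S0": 0.01}] * 5 + [{"S0": 0.5}] * 3
        assert regressor_reliance(series)["S0"]

    def test_alternating_significance_not_relied_upon(self):
        series = [{"S0": p} for p in [0.01, 0.5] * 4]
        assert not regressor_reliance(series)["S0"]

    def test_four_consecutive_then_gap_not_enough(self):
        series = [{"S0": 0.01}] * 4 + [{"S0": 0.5}] + [{"S0": 0.01}] * 4
        assert not regressor_reliance(series)["S0"]

    def test_shuffle_keeps_regressors_and_choice_multiset(self, rng):
        trials = generate_policy_trials(200, 1.0, 0.5, 0.0, rng)
        design = build_design(trials)
        shuffled = shuffle_control(design, rng)
        assert np.array_equal(shuffled.X, design.X)
        assert sorted(shuffled.y) == sorted(design.y)

    def test_identity_permutation_preserves_design(self, rng):
        trials = generate_policy_trials(200, 1.0, 0.5, 0.0, rng)
        design = build_design(trials)

        class IdentityRng:
            def permutation(self, n):
                return np.arange(n)

        shuffled = shuffle_control(design, IdentityRng())
        assert np.array_equal(shuffled.y, design.y)


class TestReducedModelSufficiency:
    def test_reduced_model_matches_full_on_reduced_generated_data(self):
        """When behavior is generated from stimulus + 1-back choice alone,
        the {S0, A1, bias} model predicts as well as the full model."""
        rng = np.random.default_rng(17)
        trials = generate_policy_trials(1040, 2.0, 0.8, 0.2, rng)
        gaps = []
        for start in (0, 520):
            design = build_design(trials[start:start + 520])
            full = crossval_predict(design)
            reduced = crossval_predict(design.subset(["S0", "A1"]))
            gaps.append(full - reduced)
        assert max(gaps) < 0.02
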