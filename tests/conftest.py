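import numpy as np
import pytest

from homecage.trial_engine import (
    Choice,
    Contingency,
    Outcome,
    PolePosition,
    Stage,
    TrialRecord,
    TrialType,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_trial(
    index: int,
    trial_type: TrialType,
    choice: Choice,
    contingency: Contingency = Contingency.STANDARD,
) -> TrialRecord:
    """Minimal scored/ignore trial record for analysis-layer tests."""
    if choice is Choice.IGNORE:
        outcome = Outcome.IGNORE
    else:
        correct = (choice is Choice.LEFT) == (trial_type is TrialType.LICK_LEFT)
        outcome = Outcome.CORRECT if correct else Outcome.ERROR
    if contingency is Contingency.STANDARD:
        pole = (PolePosition.ANTERIOR if trial_type is TrialType.LICK_LEFT
                else PolePosition.POSTERIOR)
    else:
        pole = (PolePosition.POSTERIOR if trial_type is TrialType.LICK_LEFT
                else PolePosition.ANTERIOR)
    return TrialRecord(
        trial_index=index,
        trial_type=trial_type,
        pole_position=pole,
        contingency=contingency,
        stage=Stage.DISCRIMINATION,
        delay_duration=0.2,
        lick_events=[],
        choice=choice,
        outcome=outcome,
        rewarded=outcome is Outcome.CORRECT,
    )


@pytest.fixture
def make_trial_factory():
    return make_trial
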