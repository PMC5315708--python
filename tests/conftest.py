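import numpy as np
import pytest

from scopemetrics import EventRecord, TrialRecording


def build_trial(
    duration=10.0,
    rate=50.0,
    endoscope=None,
    instruments=None,
    left=None,
    right=None,
    events=(),
    t=None,
    surgeon_id="s1",
    group="new",
    exercise_id="ex",
    overall_score=None,
):
    """Construct a trial from optional component arrays (defaults stationary)."""
    if t is None:
        n = int(round(duration * rate)) + 1
        t = np.arange(n) / rate
    else:
        t = np.asarray(t, float)
        n = len(t)
    zeros = np.zeros((n, 3))
    if instruments is None:
        instruments = zeros[:, None, :]
    instruments = np.asarray(instruments, float)
    if instruments.ndim == 2:
        instruments = instruments[:, None, :]
    return TrialRecording(
        surgeon_id=surgeon_id,
        group=group,
        exercise_id=exercise_id,
        sample_rate=rate,
        t=t,
        left_hand=zeros if left is None else left,
        right_hand=zeros if right is None else right,
        instruments=instruments,
        endoscope=zeros if endoscope is None else endoscope,
        events=[EventRecord(*e) if not isinstance(e, EventRecord) else e for e in events],
        overall_score=overall_score,
    )


@pytest.fixture
def trial_factory():
    return build_trial
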