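import numpy as np
import pytest

import p300wave as pw


@pytest.fixture(scope="session")
def small_session() -> pw.EEGStream:
    """A compact pseudo-real session: 4 trials, 10 sequences, 2 channels."""
    return pw.simulate_session(n_trials=4, n_sequences=10, n_channels=2, seed=3)


@pytest.fixture(scope="session")
def processed(small_session) -> pw.EEGStream:
    """The small session filtered and downsampled to 16 Hz."""
    return pw.preprocess_session(small_session)


@pytest.fixture(scope="session")
def segments(processed) -> list[pw.Segment]:
    """1-s segments of the processed small session."""
    return pw.extract_segments(processed)


@pytest.fixture(scope="session")
def averaged_channel(segments, processed) -> np.ndarray:
    """One averaged target-class channel vector (16 samples at 16 Hz)."""
    schedule = processed.schedule
    row_id, _ = pw.letter_position(schedule.trials[0].target)
    trial0 = [s for s in segments if s.trial_index == 0]
    return pw.ensemble_average(trial0, row_id).data[0]
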