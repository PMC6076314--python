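import numpy as np
import pytest

from gazedecode import (GeneratorParams, build_schedule, preprocess_dataset,
                        simulate_recording)
from gazedecode.preprocess import TrialTensor


@pytest.fixture(scope="session")
def small_schedule():
    """1 session x 4 runs of the standard 8-orientation design."""
    return build_schedule(sessions=1, runs_per_session=4, seed=11)


@pytest.fixture(scope="session")
def null_recordings(small_schedule):
    return simulate_recording(small_schedule, seed=11)


@pytest.fixture(scope="session")
def null_trials(small_schedule, null_recordings):
    return preprocess_dataset(null_recordings, small_schedule)


@pytest.fixture(scope="session")
def quiet_params():
    """Generator with every stochastic component silenced."""
    return GeneratorParams(
        microsaccade_rate=0.0, drift_speed=0.0, tremor_amplitude=0.0,
        blink_rate=0.0, pupil_noise=0.0,
    )


def make_trial(data, trial=0, run=0, orientation=0.0, fs=256.0) -> TrialTensor:
    """Construct a trial tensor directly from a (6, n) array."""
    return TrialTensor(trial=trial, run=run, orientation=orientation,
                       data=np.asarray(data, dtype=float), sampling_rate=fs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
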