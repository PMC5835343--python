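import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from gamblerp.pipeline import CHANNELS, EpochSet
from gamblerp.simulate_eeg import NoiseModel
from gamblerp.task import TaskParams, control_profile, simulate_session


@pytest.fixture(scope="session")
def params():
    return TaskParams()


@pytest.fixture(scope="session")
def session_trials(params):
    """One deterministic control session (160 trials)."""
    return simulate_session(params, control_profile(), seed=7, participant_id=0)


@pytest.fixture(scope="session")
def quiet_noise():
    """Background-only noise: no blinks or muscle bursts, mild pink noise."""
    return NoiseModel(
        pink_noise_scale_uV=4.0,
        alpha_amp_uV=1.0,
        blink_rate_per_min=0.0,
        blink_amp_uV=0.0,
        muscle_burst_rate_per_min=0.0,
        muscle_amp_uV=0.0,
        sensor_sd_uV=1.0,
    )


def make_epochs(data, fs=1024.0, trigger="S", conditions=None, **kw):
    data = np.asarray(data, dtype=float)
    if conditions is None:
        conditions = np.array(["HF"] * len(data), dtype=object)
    return EpochSet(
        data=data,
        fs=fs,
        trigger=trigger,
        conditions=np.asarray(conditions, dtype=object),
        ch_names=CHANNELS[: data.shape[1]],
        **kw,
    )
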