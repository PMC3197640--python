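import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ehtlab import synthetic
from ehtlab.mechanics import DEFAULT_GEOMETRY
from ehtlab.synthetic import generate_trace


@pytest.fixture(scope="session")
def default_recording():
    """One default-preset 60-s recording with its ground truth."""
    return generate_trace(synthetic.DEFAULT_SCHEDULE, synthetic.DEFAULT_TWITCH,
                          duration=60.0, seed=1)


@pytest.fixture(scope="session")
def noiseless_recording():
    """Noise-free 60-s recording for round-trip checks."""
    return generate_trace(synthetic.DEFAULT_SCHEDULE, synthetic.DEFAULT_TWITCH,
                          duration=60.0, noise_sd=0.0, seed=2)


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture
def single_twitch_trace():
    """A lone noiseless twitch centred in a 6-s trace."""
    def make(params=synthetic.DEFAULT_TWITCH, dt=0.01):
        schedule = synthetic.BeatSchedule(base_frequency=1.0 / 3.0,
                                          interval_cv=0.0)
        trace, truth = generate_trace(schedule, params, duration=6.0, dt=dt,
                                      noise_sd=0.0, seed=0)
        assert truth.event_times.size >= 1
        return trace, truth
    return make
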