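import numpy as np
import pytest

from ellnet import ModelConfig
from ellnet.spiketrains import SpikeTrain


@pytest.fixture(scope="session")
def default_config() -> ModelConfig:
    return ModelConfig()


def random_train(rng, duration_ms=1000.0, rate_hz=20.0, neuron_id=0, trial_id=0):
    """Homogeneous Poisson train helper used across test modules."""
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    times = np.sort(rng.uniform(0.0, duration_ms, size=n))
    times = times[np.concatenate(([True], np.diff(times) > 0))]
    return SpikeTrain(times, duration_ms, neuron_id=neuron_id, trial_id=trial_id)
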