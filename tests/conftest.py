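import numpy as np
import pytest

from spikeomega import SimConfig, generate_session


@pytest.fixture(scope="session")
def tuned_session():
    """Small session with real reward and direction effects, spikes and eye traces."""
    cfg = SimConfig(
        n_trials=60,
        baseline_rate_hz=30.0,
        reward_gain=2.0,
        direction_tuning_depth=0.5,
        seed=11,
        catchup_saccade_rate=1.0,
    )
    return generate_session(cfg, n_neurons=2, with_eye_traces=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
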