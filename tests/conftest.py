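import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gazesteer as gs

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def slalom():
    return gs.build_slalom_track()


@pytest.fixture(scope="session")
def sbend():
    return gs.build_sbend_track()


@pytest.fixture(scope="session")
def sbend_small():
    """Four-curve S-bend: same geometry statistics, much shorter runs."""
    return gs.build_sbend_track(n_curves=4)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Deterministic slalom driver: no gaze/motor noise, no glances."""
    return gs.default_config(
        "exp1",
        gaze_noise_sd=0.0,
        motor_noise_sd=0.0,
        lookahead_prob=0.0,
        horizon_glance_prob=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_trial(slalom, noiseless_cfg):
    rng = np.random.default_rng(11)
    return gs.generate_human_trial(slalom, noiseless_cfg, rng)


@pytest.fixture(scope="session")
def noisy_trials(slalom):
    """Small default-noise synthetic slalom dataset (2 x 2 trials)."""
    cfg = gs.default_config(
        "exp1", n_participants=2, trials_per_participant=2, seed=7
    )
    return gs.generate_dataset("exp1", cfg)
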