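"""Shared fixtures: seeded synthetic trials reused across the suite."""

import numpy as np
import pytest

from gaitphase.pipeline import Trial, make_trial
from gaitphase.simulate import generate_trial, preset


@pytest.fixture(scope="session")
def clean_profile():
    """Healthy preset with every noise source disabled."""
    return preset("healthy", seed=7, gyro_noise_sd=0.0, accel_noise_sd=0.0,
                  fraction_jitter_sd=0.0, stride_time_jitter_sd=0.0)


@pytest.fixture(scope="session")
def clean_trial(clean_profile) -> Trial:
    imu, fsw, truth = generate_trial(clean_profile, 12)
    return make_trial(imu, fsw, truth)


@pytest.fixture(scope="session")
def noisy_trial() -> Trial:
    imu, fsw, truth = generate_trial(preset("healthy", seed=3), 20)
    return make_trial(imu, fsw, truth)


@pytest.fixture(scope="session")
def healthy_pool() -> list[Trial]:
    """Five default-noise healthy trials for HMM training fixtures."""
    rng = np.random.default_rng(10)
    return [make_trial(*generate_trial(preset("healthy"), 15, rng=rng)[:2])
            for _ in range(5)]


@pytest.fixture(scope="session")
def trained_spt(healthy_pool):
    from gaitphase.hmm import train_spt
    return train_spt([(t.imu, t.reference) for t in healthy_pool[:4]],
                     max_iter=10)
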