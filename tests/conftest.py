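import numpy as np
import pytest

import neurotrace as nt
from neurotrace.synthetic import (
    NoiseSpec,
    ToneScheduleParams,
    default_templates,
    generate_oddball_eeg,
    generate_tone_schedule,
)

SMALL_PARAMS = ToneScheduleParams(n_blocks=2, tones_per_block=30)


@pytest.fixture(scope="session")
def small_session():
    """A cheap oddball session (60 tones, 8 channels, 250 Hz) with truth."""
    schedule = generate_tone_schedule(SMALL_PARAMS, seed=7)
    rec, truth = generate_oddball_eeg(
        schedule, noise_spec=NoiseSpec(), n_channels=8, fs_hz=250.0, seed=8
    )
    return rec, truth


@pytest.fixture(scope="session")
def default_session():
    """One full-scale session (600 tones, 32 channels, 500 Hz)."""
    schedule = generate_tone_schedule(ToneScheduleParams(), seed=11)
    rec, truth = generate_oddball_eeg(schedule, seed=12)
    return rec, truth


@pytest.fixture(scope="session")
def default_epochs(default_session):
    rec, truth = default_session
    filt = nt.bandpass(rec)
    return nt.cut_epochs(filt, (-0.2, 0.8), label_map={nt.STANDARD: 0, nt.TARGET: 1})


def toy_gaussians(n_per_class=200, d=2, delta=3.0, seed=0):
    """Two spherical Gaussian classes separated along the first axis."""
    rng = np.random.default_rng(seed)
    mu0 = np.zeros(d)
    mu1 = np.r_[delta, np.zeros(d - 1)]
    X = np.vstack([rng.normal(size=(n_per_class, d)) + mu0,
                   rng.normal(size=(n_per_class, d)) + mu1])
    y = np.r_[np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)]
    order = rng.permutation(2 * n_per_class)
    return X[order], y[order]
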