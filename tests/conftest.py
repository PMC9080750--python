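import numpy as np
import pytest

from buzzpause.synth import render_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """Small rendered dataset at ~30 dB SNR with full ground truth."""
    return render_dataset(n_bats=4, n_dates=2, n_attacks=10, noise_rms=0.0087, seed=202)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free rendering: detection should be measurement-exact."""
    return render_dataset(n_bats=3, n_dates=2, n_attacks=6, noise_rms=0.0, seed=11)


def calibrated_table(rng, n_per_level=(37, 33, 17), means=(200.0, 153.0, 114.0),
                     n_dates=3, bats_per_date=2):
    """Observation table at the reference calibration, zero random-effect SD."""
    from buzzpause.calibration import simulate_calibrated_dataset

    levels = ("captured", "dropped", "failed")
    return simulate_calibrated_dataset(
        counts=dict(zip(levels, n_per_level)), means=dict(zip(levels, means)),
        rng=rng, n_dates=n_dates, bats_per_date=bats_per_date,
    )
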