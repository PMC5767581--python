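import numpy as np
import pytest

from cmc import Recording, SimulationParams, segment_epochs, simulate_session


@pytest.fixture(scope="session")
def small_params():
    """A small but structurally complete session: 12 electrodes, 3 trials."""
    return SimulationParams(montage_size=12, n_trials=3, n_runs=1, seed=42)


@pytest.fixture(scope="session")
def small_session(small_params):
    return simulate_session(small_params)


@pytest.fixture(scope="session")
def small_epochs(small_session):
    rec, _ = small_session
    return segment_epochs(rec)


def make_recording(n_channels=3, n_samples=4000, fs=1000.0, seed=0, kinds=None):
    """Plain white-noise recording with a single trial spanning everything."""
    rng = np.random.default_rng(seed)
    kinds = kinds or ["EEG"] * n_channels
    channels = [(f"E{i + 1:03d}" if k == "EEG" else k, k) for i, k in enumerate(kinds)]
    return Recording(
        fs=fs,
        channels=channels,
        data=rng.standard_normal((n_channels, n_samples)),
        events=[(0, "trial_start"), (n_samples, "trial_end")],
    )
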