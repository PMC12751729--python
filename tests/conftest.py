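import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scdeeg.core import CHANNELS_1020, EpochSet
from scdeeg.synthetic import CohortSpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A miniature cohort spec for fast end-to-end tests."""
    return CohortSpec(n_pos=5, n_neg=8, duration=136.0, artifact_rate=0.5, seed=7)


def make_epochset(data: np.ndarray, fs: float = 250.0, subject_id: str = "test") -> EpochSet:
    """Wrap an (epochs, channels, samples) array as an EpochSet."""
    n_epochs, n_ch, n_samp = data.shape
    channels = CHANNELS_1020[:n_ch] if n_ch <= 19 else tuple(
        f"ch{i}" for i in range(n_ch)
    )
    return EpochSet(
        subject_id=subject_id,
        epochs=data,
        fs=fs,
        epoch_length=n_samp / fs,
        channels=channels,
        selected_indices=np.arange(n_epochs),
    )


@pytest.fixture
def sine_epochs():
    """60 two-second epochs of a unit 10 Hz sinusoid on 2 channels (plus tiny noise)."""
    fs, n_epochs, n_samp = 250.0, 60, 500
    t = np.arange(n_epochs * n_samp) / fs
    x = np.sin(2 * np.pi * 10.0 * t)
    rng = np.random.default_rng(0)
    data = np.stack([x, x.copy()])
    data = data + 1e-6 * rng.standard_normal(data.shape)
    epochs = data.reshape(2, n_epochs, n_samp).transpose(1, 0, 2)
    return make_epochset(epochs, fs)
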