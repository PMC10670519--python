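import numpy as np
import pytest

from vreeg.preprocess import EpochSet, Marker, Recording
from vreeg.synth import SynthConfig, alpha_contrast_effects, generate_recording


@pytest.fixture(scope="session")
def small_cfg():
    """A light generator configuration for fast structural tests."""
    return SynthConfig(n_subjects=2, trial_seconds=10.0, baseline_seconds=5.0,
                       fs_raw=128.0, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    return generate_recording(small_cfg, 0)


@pytest.fixture(scope="session")
def alpha_cfg():
    """Light configuration with distinct per-scene alpha-power offsets."""
    return SynthConfig(n_subjects=2, trial_seconds=10.0, baseline_seconds=5.0,
                       fs_raw=128.0, band_effects=alpha_contrast_effects(),
                       seed=11)


def make_epochs(data, fs=128.0, scenes=None, subject=0, baseline=None,
                montage=None):
    """Wrap a trials x channels x samples array into an EpochSet."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_samp = data.shape
    scenes = scenes or [f"S{i}" for i in range(n_trials)]
    labels = [Marker(onset=i * n_samp / fs, duration=n_samp / fs,
                     scene=s, region="R", subject=subject)
              for i, s in enumerate(scenes)]
    return EpochSet(
        epochs=data, fs=fs, window_seconds=n_samp / fs, labels=labels,
        channel_labels=tuple(f"CH{i}" for i in range(n_ch)),
        baseline_means=baseline,
        montage=montage or {},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
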