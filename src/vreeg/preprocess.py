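"""Raw-recording preprocessing: re-reference, resample, filter, ICA, epoch.

The chain mirrors a conventional consumer-EEG workflow: the amplifier ships
differentially mounted signals (channel minus CMS), which are downsampled to
a 128 Hz analysis rate, low-pass filtered at 45 Hz with a zero-phase
windowed-sinc FIR, cut into fixed 90-s task epochs, cleaned of ocular
artifacts with ICA, and baseline-corrected against the pre-experiment rest
segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

from .channels import FRONTAL_CHANNELS


@dataclass
class Marker:
    """A labelled time segment of a continuous recording (seconds)."""

    onset: float
    duration: float
    scene: str
    region: str
    subject: int


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is channels x samples; ``markers`` hold the baseline segment
    (scene == "baseline") and one entry per task trial.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    markers: list[Marker] = field(default_factory=list)
    montage: dict[str, tuple[float, float]] = field(default_factory=dict)
    reference_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows for "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.data.shape[1] / self.fs
        for m in self.markers:
            if not 0 <= m.onset <= dur:
                raise ValueError(f"marker onset {m.onset}s outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None


@dataclass
class EpochSet:
    """Fixed-length task epochs: trials x channels x samples."""

    epochs: np.ndarray
    fs: float
    window_seconds: float
    labels: list[Marker]
    channel_labels: tuple[str, ...]
    baseline_means: np.ndarray | None = None
    montage: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        n_expected = int(round(self.window_seconds * self.fs))
        if self.epochs.shape[0] and self.epochs.shape[2] != n_expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != "
                f"window {self.window_seconds}s x {self.fs}Hz"
            )
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("one label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class ICAReport:
    removed: list[int]
    correlations: np.ndarray
    threshold: float


def rereference_pair(recording: Recording, a: str, b: str) -> np.ndarray:
    """Differential signal a-b; the common CMS term cancels algebraically."""
    ia = recording.channel_index(a)
    ib = recording.channel_index(b)
    return recording.data[ia] - recording.data[ib]


def resample(recording: Recording, fs_out: float) -> Recording:
    """Polyphase anti-aliased downsampling; markers stay in seconds."""
    if fs_out > recording.fs:
        raise ValueError("upsampling not supported")
    if fs_out == recording.fs:
        return replace(recording, data=recording.data.copy())
    frac = Fraction(fs_out / recording.fs).limit_denominator(10_000)
    data = signal.resample_poly(
        recording.data, frac.numerator, frac.denominator, axis=1
    )
    return Recording(
        data=data,
        fs=fs_out,
        channel_labels=recording.channel_labels,
        markers=list(recording.markers),
        montage=dict(recording.montage),
        reference_labels=recording.reference_labels,
    )


def _sinc_lowpass_taps(cutoff: float, fs: float) -> np.ndarray:
    # Kaiser-windowed sinc sized for >=60 dB single-pass stopband rejection
    # beyond 1.2x cutoff; filtfilt application doubles that.
    nyq = fs / 2.0
    width = 0.4 * cutoff / nyq
    numtaps, beta = signal.kaiserord(60.0, width)
    numtaps |= 1  # odd length -> symmetric, integer group delay
    return signal.firwin(numtaps, 1.1 * cutoff / nyq, window=("kaiser", beta))


def lowpass(recording: Recording, cutoff: float) -> Recording:
    """Zero-phase windowed-sinc FIR low-pass below the Nyquist frequency."""
    if cutoff >= recording.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {recording.fs / 2} Hz")
    taps = _sinc_lowpass_taps(cutoff, recording.fs)
    data = signal.filtfilt(taps, [1.0], recording.data, axis=1)
    return replace(recording, data=data)


def lowpass_waveform(waveform: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Zero-phase sinc low-pass of a channels x samples array."""
    taps = _sinc_lowpass_taps(cutoff, fs)
    return signal.filtfilt(taps, [1.0], np.atleast_2d(waveform), axis=-1)


def epoch(recording: Recording, window_seconds: float = 90.0) -> EpochSet:
    """Cut one epoch per task marker: the first *window_seconds* of the trial.

    The baseline marker (scene == "baseline") is not epoched; its per-channel
    mean is stored for later baseline correction.
    """
    n_win = int(round(window_seconds * recording.fs))
    task = [m for m in recording.markers if m.scene != "baseline"]
    short = [m for m in task if m.duration < window_seconds - 1e-9]
    if short:
        names = ", ".join(f"{m.scene}@{m.onset}s({m.duration}s)" for m in short)
        raise ValueError(f"trial(s) shorter than {window_seconds}s window: {names}")
    epochs = np.empty((len(task), recording.n_channels, n_win))
    for i, m in enumerate(task):
        start = int(round(m.onset * recording.fs))
        epochs[i] = recording.data[:, start:start + n_win]

    baseline_means = None
    base = [m for m in recording.markers if m.scene == "baseline"]
    if base:
        b = base[0]
        s0 = int(round(b.onset * recording.fs))
        s1 = s0 + int(round(b.duration * recording.fs))
        baseline_means = recording.data[:, s0:s1].mean(axis=1)

    return EpochSet(
        epochs=epochs,
        fs=recording.fs,
        window_seconds=window_seconds,
        labels=task,
        channel_labels=recording.channel_labels,
        baseline_means=baseline_means,
        montage=dict(recording.montage),
    )


def remove_artifacts_ica(
    epochs: EpochSet,
    frontal_channels: Sequence[str] = FRONTAL_CHANNELS,
    corr_threshold: float = 0.7,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[EpochSet, ICAReport]:
    """Zero ICA components whose time course tracks the mean frontal signal.

    Components are estimated on the concatenated epochs; any component whose
    absolute Pearson correlation with the mean of *frontal_channels* exceeds
    *corr_threshold* is removed before back-projection.  Blink/EOG activity
    projects dominantly onto the frontal row, so a planted ocular source is
    captured by a single component.
    """
    from sklearn.decomposition import FastICA

    if epochs.epochs.shape[1] < 2:
        raise ValueError("ICA needs at least two channels")
    n_trials, n_ch, n_samp = epochs.epochs.shape
    X = epochs.epochs.transpose(1, 0, 2).reshape(n_ch, n_trials * n_samp).T
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in epochs")

    ica = FastICA(
        n_components=n_ch,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=1e-4,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings are benign here
        S = ica.fit_transform(X)

    idx = [epochs.channel_labels.index(c)
           for c in frontal_channels if c in epochs.channel_labels]
    if not idx:
        raise ValueError("no frontal channels present")
    ref = X[:, idx].mean(axis=1)
    ref = ref - ref.mean()
    denom = np.linalg.norm(ref)
    corrs = np.zeros(S.shape[1])
    for k in range(S.shape[1]):
        s = S[:, k] - S[:, k].mean()
        ns = np.linalg.norm(s)
        corrs[k] = abs(ref @ s) / (denom * ns) if ns > 0 and denom > 0 else 0.0

    removed = [int(k) for k in np.flatnonzero(corrs > corr_threshold)]
    S_clean = S.copy()
    S_clean[:, removed] = 0.0
    X_clean = ica.inverse_transform(S_clean)

    cleaned = X_clean.T.reshape(n_ch, n_trials, n_samp).transpose(1, 0, 2)
    out = EpochSet(
        epochs=cleaned,
        fs=epochs.fs,
        window_seconds=epochs.window_seconds,
        labels=list(epochs.labels),
        channel_labels=epochs.channel_labels,
        baseline_means=epochs.baseline_means,
        montage=dict(epochs.montage),
    )
    return out, ICAReport(removed=removed, correlations=corrs,
                          threshold=corr_threshold)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the stored per-channel pre-experiment mean from every epoch."""
    if epochs.baseline_means is None:
        raise ValueError("baseline_means not populated")
    bm = np.asarray(epochs.baseline_means, dtype=float)
    if bm.shape != (epochs.epochs.shape[1],):
        raise ValueError("one baseline mean per channel required")
    return EpochSet(
        epochs=epochs.epochs - bm[None, :, None],
        fs=epochs.fs,
        window_seconds=epochs.window_seconds,
        labels=list(epochs.labels),
        channel_labels=epochs.channel_labels,
        baseline_means=np.zeros_like(bm),
        montage=dict(epochs.montage),
    )


def preprocess_recording(
    recording: Recording,
    fs_out: float = 128.0,
    lowpass_hz: float = 45.0,
    window_seconds: float = 90.0,
    run_ica: bool = True,
    ica_threshold: float = 0.7,
    seed: int = 0,
) -> tuple[EpochSet, ICAReport | None]:
    """Full chain: resample -> low-pass -> epoch -> ICA -> baseline-correct.

    The input is assumed already differentially mounted (channel minus CMS),
    as delivered by the acquisition hardware, so no re-referencing step is
    applied by default.
    """
    rec = resample(recording, fs_out)
    rec = lowpass(rec, lowpass_hz)
    eps = epoch(rec, window_seconds)
    report = None
    if run_ica and eps.n_epochs:
        eps, report = remove_artifacts_ica(
            eps, corr_threshold=ica_threshold, seed=seed
        )
    if eps.baseline_means is not None:
        eps = baseline_correct(eps)
    return eps, report
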