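"""Time- and frequency-domain EEG features.

Per channel, the time-domain block holds ten measures: power, mean,
population standard deviation, mean absolute first and second differences
(raw and sigma-normalised), and the three Hjorth parameters (activity,
mobility, complexity).  Activity equals the population variance exactly, so
variance is not duplicated as a separate column; with 32 channels the block
is 320 columns wide.

The frequency-domain block combines an FFT-derived set (per-channel relative
band power and band spectral entropy over the five canonical bands, plus
left-right band-power asymmetry over eight homologous pairs: 160+160+40=360
columns) with the raw Welch spectrum (64-sample Hamming windows, hop 32:
33 bins x 32 channels = 1056 columns), 1416 columns in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .channels import ASYMMETRY_PAIRS, BAND_EDGES
from .preprocess import EpochSet

TIME_MEASURES = ("power", "mean", "std", "d1", "d1n", "d2", "d2n",
                 "activity", "mobility", "complexity")


@dataclass
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band {self.name}: [{self.low}, {self.high}]")


def default_bands() -> list[BandDefinition]:
    return [BandDefinition(n, lo, hi) for n, (lo, hi) in BAND_EDGES.items()]


@dataclass
class Spectrum:
    """A spectral representation: FFT coefficients or a PSD estimate."""

    frequencies: np.ndarray
    values: np.ndarray
    method: str  # "fft" | "welch" | "periodogram"
    n_source: int


def time_features(epoch: np.ndarray, fs: float) -> pd.DataFrame:
    """The ten time-domain measures for each row of a channels x samples epoch.

    Constant channels have zero variance; their normalised differences and
    Hjorth mobility/complexity are reported as 0 with a warning so that
    downstream feature tables stay complete.
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    mu = x.mean(axis=1)
    var = x.var(axis=1)            # population (1/N)
    sd = np.sqrt(var)
    power = (x ** 2).mean(axis=1)
    dx = np.diff(x, axis=1)
    ddx = np.diff(x, n=2, axis=1)
    d1 = np.abs(dx).mean(axis=1)
    d2 = np.abs(x[:, 2:] - x[:, :-2]).mean(axis=1)

    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("constant channel(s): normalised differences and "
                      "mobility/complexity set to 0", RuntimeWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        d1n = np.where(degenerate, 0.0, d1 / sd)
        d2n = np.where(degenerate, 0.0, d2 / sd)
        var_d = dx.var(axis=1)
        var_dd = ddx.var(axis=1)
        mob = np.where(degenerate, 0.0, np.sqrt(var_d / var))
        mob_d = np.where(var_d == 0, 0.0, np.sqrt(var_dd / var_d))
        comp = np.where(mob == 0, 0.0, mob_d / mob)

    return pd.DataFrame({
        "power": power, "mean": mu, "std": sd,
        "d1": d1, "d1n": d1n, "d2": d2, "d2n": d2n,
        "activity": var, "mobility": mob, "complexity": comp,
    })


def fft_transform(x: np.ndarray) -> Spectrum:
    """Discrete Fourier transform X_k, k = 0..N-1, of a 1-D signal."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("need a non-empty 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    X = np.fft.fft(x)
    return Spectrum(frequencies=np.arange(x.size, dtype=float),
                    values=X, method="fft", n_source=x.size)


def spectral_entropy(psd: Spectrum | np.ndarray) -> float:
    """Shannon entropy (bits) of the PSD normalised to a unit distribution."""
    p = psd.values if isinstance(psd, Spectrum) else np.asarray(psd, float)
    p = np.real(np.asarray(p, dtype=float))
    if np.any(p < -1e-12):
        raise ValueError("PSD must be nonnegative")
    p = np.clip(p, 0.0, None)
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total power")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def welch_psd(x: np.ndarray, fs: float, window_samples: int = 64,
              hop_samples: int = 32) -> Spectrum:
    """Hamming-windowed averaged periodogram (Welch), 50% overlap default."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < window_samples:
        raise ValueError("signal shorter than the Welch window")
    f, p = sps.welch(x, fs=fs, window="hamming", nperseg=window_samples,
                     noverlap=window_samples - hop_samples, axis=-1)
    return Spectrum(frequencies=f, values=p, method="welch",
                    n_source=x.shape[-1])


def band_power(psd: Spectrum, band: BandDefinition,
               total_range: tuple[float, float] = (1.0, 45.0)) -> float:
    """Fraction of 1-45 Hz power inside *band* (half-open [low, high) bins;
    the top band includes its upper edge)."""
    f = psd.frequencies
    p = np.real(psd.values)
    if band.low < f[0] - 1e-9 or band.high > f[-1] + 1e-9:
        raise ValueError(f"band {band.name} outside the PSD grid")
    hi_inclusive = band.high >= total_range[1]
    in_band = (f >= band.low) & ((f <= band.high) if hi_inclusive
                                 else (f < band.high))
    in_total = (f >= total_range[0]) & (f <= total_range[1])
    denom = p[..., in_total].sum(axis=-1)
    if np.any(denom <= 0):
        raise ValueError("no power in the reference range")
    return p[..., in_band].sum(axis=-1) / denom


def _band_masks(f: np.ndarray, bands: list[BandDefinition]):
    top = max(b.high for b in bands)
    masks = {}
    for b in bands:
        hi_inc = b.high >= top
        masks[b.name] = (f >= b.low) & ((f <= b.high) if hi_inc
                                        else (f < b.high))
    total = (f >= min(b.low for b in bands)) & (f <= top)
    return masks, total


def _bandpass(data: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    nyq = fs / 2.0
    sos = sps.butter(4, [band.low / nyq, min(band.high, 0.99 * nyq) / nyq],
                     btype="band", output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def extract_features(
    epochs: EpochSet,
    bands: list[BandDefinition] | None = None,
    domain: str = "both",
    band_filtered: str | None = None,
    sub_epoch_seconds: float | None = None,
    welch_window: int = 64,
    welch_hop: int = 32,
) -> pd.DataFrame:
    """Instance x feature table from an epoch set.

    One row per epoch, or per non-overlapping *sub_epoch_seconds* window
    when given (the trial index then serves as the bag id for
    multi-instance learning).  Columns are named ``CH.measure[.band]``;
    label columns scene/region/subject/bag_id are appended last.

    With ``band_filtered`` set, signals are zero-phase band-passed to that
    band before any feature is computed (per-band classification runs).
    """
    if domain not in {"time", "frequency", "both"}:
        raise ValueError(f"unknown domain {domain!r}")
    bands = bands if bands is not None else default_bands()
    band_map = {b.name: b for b in bands}
    if band_filtered is not None and band_filtered not in band_map:
        raise ValueError(f"unknown band {band_filtered!r}")

    chs = epochs.channel_labels
    fs = epochs.fs
    rows, meta = [], []
    for trial_idx in range(epochs.n_epochs):
        lab = epochs.labels[trial_idx]
        sig = epochs.epochs[trial_idx]
        if band_filtered is not None:
            sig = _bandpass(sig, fs, band_map[band_filtered])
        if sub_epoch_seconds is None:
            pieces = [sig]
        else:
            n_sub = int(round(sub_epoch_seconds * fs))
            k = sig.shape[1] // n_sub
            pieces = [sig[:, i * n_sub:(i + 1) * n_sub] for i in range(k)]
        for piece in pieces:
            rows.append(piece)
            meta.append({"scene": lab.scene, "region": lab.region,
                         "subject": lab.subject,
                         "bag_id": f"s{lab.subject}t{trial_idx}"})

    blocks: list[pd.DataFrame] = []
    if rows:
        stack = np.stack(rows)                      # instances x ch x samples
        n_inst = stack.shape[0]
        if domain in {"time", "both"}:
            flat = stack.reshape(-1, stack.shape[2])
            tf = time_features(flat, fs)
            cols = {}
            for j, m in enumerate(TIME_MEASURES):
                vals = tf[m].to_numpy().reshape(n_inst, len(chs))
                for c, ch in enumerate(chs):
                    cols[f"{ch}.{m}"] = vals[:, c]
            blocks.append(pd.DataFrame(cols))
        if domain in {"frequency", "both"}:
            blocks.append(_frequency_block(stack, fs, chs, bands,
                                           welch_window, welch_hop))
    table = (pd.concat(blocks, axis=1) if blocks
             else pd.DataFrame(index=range(len(meta))))
    labels = pd.DataFrame(meta, columns=["scene", "region", "subject",
                                         "bag_id"])
    out = pd.concat([table, labels], axis=1)
    if out.columns.duplicated().any():
        raise ValueError("duplicate feature names")
    return out


def _frequency_block(stack: np.ndarray, fs: float, chs, bands,
                     welch_window: int, welch_hop: int) -> pd.DataFrame:
    n_inst, n_ch, n_samp = stack.shape
    cols: dict[str, np.ndarray] = {}

    # FFT-derived set: periodogram |X_k|^2 on the full window.
    X = np.fft.rfft(stack, axis=-1)
    pxx = (np.abs(X) ** 2) / n_samp
    f = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    masks, total_mask = _band_masks(f, bands)
    total = pxx[..., total_mask].sum(axis=-1)
    total = np.where(total > 0, total, 1.0)

    bp = {}
    for b in bands:
        bp[b.name] = pxx[..., masks[b.name]].sum(axis=-1) / total
        for c, ch in enumerate(chs):
            cols[f"{ch}.bandpower.{b.name}"] = bp[b.name][:, c]
    for b in bands:
        sub = pxx[..., masks[b.name]]
        tot = sub.sum(axis=-1, keepdims=True)
        p = sub / np.where(tot > 0, tot, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=-1)
        for c, ch in enumerate(chs):
            cols[f"{ch}.bandentropy.{b.name}"] = ent[:, c]
    ch_index = {ch: i for i, ch in enumerate(chs)}
    for left, right in ASYMMETRY_PAIRS:
        if left not in ch_index or right not in ch_index:
            continue
        li, ri = ch_index[left], ch_index[right]
        for b in bands:
            l, r = bp[b.name][:, li], bp[b.name][:, ri]
            denom = np.where(l + r > 0, l + r, 1.0)
            cols[f"{left}-{right}.asymmetry.{b.name}"] = (l - r) / denom

    # Welch block: every PSD bin of every channel.
    spec = welch_psd(stack.reshape(-1, n_samp), fs,
                     window_samples=welch_window, hop_samples=welch_hop)
    pw = spec.values.reshape(n_inst, n_ch, -1)
    for c, ch in enumerate(chs):
        for k, freq in enumerate(spec.frequencies):
            cols[f"{ch}.welch.{freq:g}Hz"] = pw[:, c, k]
    return pd.DataFrame(cols)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature (non-label) column names of an extracted table."""
    labels = {"scene", "region", "subject", "bag_id"}
    return [c for c in table.columns if c not in labels]
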