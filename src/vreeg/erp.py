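"""ERP peak-latency scalp topography.

For each condition (baseline or one VR scene), the trial-averaged waveform
is low-pass filtered with a zero-phase windowed sinc at 45 Hz and, per
channel, the latency of the maximum absolute deflection within the task
window is taken.  The per-channel latencies are interpolated over the unit
scalp disk by inverse-distance weighting of the montage coordinates,
yielding a latency map rather than a voltage map: the question is *when*
each region peaks, not how strongly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochSet, lowpass_waveform


@dataclass
class TopographyMap:
    """Per-channel peak latencies plus an interpolated scalp grid."""

    channel_labels: tuple[str, ...]
    latencies: np.ndarray            # seconds, one per channel
    amplitudes: np.ndarray           # signed peak value, retained for QC
    grid: np.ndarray                 # 2-D latency grid, NaN outside the disk
    grid_x: np.ndarray
    grid_y: np.ndarray
    condition: str = ""
    flat_channels: list[str] = field(default_factory=list)


def erp_average(epochs: EpochSet, condition: str) -> np.ndarray:
    """Sample-wise mean waveform (channels x samples) for one condition."""
    idx = [i for i, m in enumerate(epochs.labels) if m.scene == condition]
    if not idx:
        raise ValueError(f"no epochs with condition {condition!r}")
    return epochs.epochs[idx].mean(axis=0)


def peak_latency_map(
    waveform: np.ndarray,
    fs: float,
    montage: dict[str, tuple[float, float]],
    channel_labels,
    lowpass_hz: float = 45.0,
    condition: str = "",
    grid_n: int = 64,
    idw_power: float = 3.0,
) -> TopographyMap:
    """Latency of the maximum absolute deflection per channel, on a grid.

    Ties break to the earliest sample.  Flat channels get latency 0 and are
    flagged.  The returned map is invariant to uniform amplitude scaling of
    the waveform.  Interpolation uses cubic inverse-distance weighting
    (*idw_power* = 3): distance-squared weighting lets far-away electrodes
    bleed into a region and washes out local latency structure.
    """
    w = np.atleast_2d(np.asarray(waveform, dtype=float))
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite waveform")
    if w.shape[0] != len(channel_labels):
        raise ValueError("one waveform row per channel required")
    if lowpass_hz is not None and lowpass_hz < fs / 2:
        w = lowpass_waveform(w, fs, lowpass_hz)

    flat = np.ptp(w, axis=1) == 0
    peak_idx = np.abs(w).argmax(axis=1)      # argmax -> earliest on ties
    lat = peak_idx / fs
    amp = w[np.arange(w.shape[0]), peak_idx]
    if flat.any():
        lat = np.where(flat, 0.0, lat)
        warnings.warn("flat channel(s): latency reported as 0",
                      RuntimeWarning)

    pos = np.array([montage[c] for c in channel_labels], dtype=float)
    ax = np.linspace(-1.0, 1.0, grid_n)
    gx, gy = np.meshgrid(ax, ax)
    inside = gx ** 2 + gy ** 2 <= 1.0
    grid = np.full((grid_n, grid_n), np.nan)
    pts = np.column_stack([gx[inside], gy[inside]])
    d2 = ((pts[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(d2)
    vals = np.empty(len(pts))
    exact = d < 1e-9
    with np.errstate(divide="ignore"):
        wgt = 1.0 / d ** idw_power
    has_exact = exact.any(axis=1)
    vals[has_exact] = lat[exact[has_exact].argmax(axis=1)]
    rest = ~has_exact
    vals[rest] = (wgt[rest] * lat).sum(axis=1) / wgt[rest].sum(axis=1)
    grid[inside] = vals

    return TopographyMap(
        channel_labels=tuple(channel_labels),
        latencies=lat,
        amplitudes=amp,
        grid=grid, grid_x=gx, grid_y=gy,
        condition=condition,
        flat_channels=[c for c, f in zip(channel_labels, flat) if f],
    )


def condition_maps(epochs: EpochSet, conditions, lowpass_hz: float = 45.0
                   ) -> dict[str, TopographyMap]:
    """Peak-latency maps for several conditions of one epoch set."""
    out = {}
    for cond in conditions:
        wav = erp_average(epochs, cond)
        out[cond] = peak_latency_map(
            wav, epochs.fs, epochs.montage, epochs.channel_labels,
            lowpass_hz=lowpass_hz, condition=cond)
    return out


def plot_topography(tmap: TopographyMap, ax=None, cmap: str = "viridis"):
    """Render a latency map; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(tmap.grid, origin="lower", extent=(-1, 1, -1, 1),
                   cmap=cmap)
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="k", lw=1)
    ax.set_title(tmap.condition or "latency (s)")
    ax.set_xticks([]), ax.set_yticks([])
    plt.colorbar(im, ax=ax, shrink=0.8, label="peak latency (s)")
    return ax
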