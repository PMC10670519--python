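"""Seeded synthetic EEG recordings and questionnaire tables.

The EEG model is deliberately second-order: each channel is a sum of
band-limited Gaussian noise processes (one per canonical band) riding on a
1/f pink background, because every downstream feature in this package
(band powers, spectral entropy, Hjorth parameters, Welch bins) depends only
on the spectral structure of the signal.  Scene/region class membership is
planted as multiplicative band-power offsets, blink artifacts as a biphasic
frontal template, and a pre-experiment rest segment precedes the five task
trials.  Questionnaires (SSQ, SAM, VRI) are drawn from simple generative
models whose scene-level severities follow the observed ordering (the
roller-coaster scene most severe, the calm viewing scene least).

No cortical source or volume-conduction modelling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .channels import (
    BAND_EDGES,
    CHANNELS_32,
    REFERENCE_LABELS,
    REGIONS,
    SCENE_TO_REGION,
    SCENES,
    montage_2d,
)
from .preprocess import Marker, Recording

#: Baseline RMS amplitude (microvolt) of each band-limited component.
BAND_RMS_UV = {
    "delta": 6.0,
    "theta": 4.0,
    "alpha": 8.0,
    "beta": 3.0,
    "gamma": 1.5,
}

#: Per-scene mean SSQ item severity on the 0-3 scale.  Derived from the
#: observed per-scene total-score ordering (raw score total / 21 subscale
#: slots): the roller coaster is most severe, the calm viewing scene least.
DEFAULT_SSQ_SEVERITY = {
    "TWD": 0.38,
    "PNI": 0.43,
    "TL": 0.12,
    "PVR": 0.40,
    "RC": 0.65,
}

#: Per-scene SAM (valence, arousal, dominance) means on the 1-9 scale,
#: consistent with each scene's valence-arousal quadrant.
DEFAULT_SAM_CENTERS = {
    "TWD": (3.0, 7.0, 5.0),
    "PNI": (3.5, 3.5, 5.0),
    "TL": (7.0, 3.0, 6.0),
    "PVR": (7.0, 7.0, 5.0),
    "RC": (7.0, 7.5, 4.0),
}

#: VRI structure: (immersion level, factor, number of items).
VRI_STRUCTURE = (
    ("engagement", "interest", 6),
    ("engagement", "time_investment", 6),
    ("engagement", "usability", 6),
    ("engrossment", "emotional_engagement", 5),
    ("engrossment", "focus_of_attention", 7),
    ("total_immersion", "presence", 8),
    ("total_immersion", "flow", 4),
)


def vri_item_map() -> pd.DataFrame:
    """Item id -> immersion level and factor for the 42-item VRI."""
    rows = []
    i = 0
    for level, factor, n in VRI_STRUCTURE:
        for _ in range(n):
            i += 1
            rows.append({"item": f"item{i:02d}", "level": level,
                         "factor": factor})
    return pd.DataFrame(rows)


def default_vri_loadings(primary: float = 0.75,
                         general: float = 0.30) -> np.ndarray:
    """Block-diagonal 42 x 7 loading matrix plus a shared general column.

    Each item loads *primary* on its own factor; the *general* loading is
    folded in through a common factor at generation time (see
    :func:`generate_questionnaires`) and is not part of this matrix.
    """
    sizes = [n for _, _, n in VRI_STRUCTURE]
    L = np.zeros((sum(sizes), len(sizes)))
    r = 0
    for j, n in enumerate(sizes):
        L[r:r + n, j] = primary
        r += n
    return L


def _zero_band_effects() -> dict[str, dict[str, float]]:
    labels = list(SCENES) + list(REGIONS)
    return {lab: {b: 0.0 for b in BAND_EDGES} for lab in labels}


def alpha_contrast_effects(step: float = 0.5) -> dict[str, dict[str, float]]:
    """Distinct per-scene alpha-band power offsets spaced by *step* (+50%)."""
    eff = _zero_band_effects()
    for i, scene in enumerate(SCENES):
        eff[scene]["alpha"] = step * i
    return eff


@dataclass
class SynthConfig:
    """Generative settings for one synthetic EEG cohort."""

    n_subjects: int = 32
    n_scenes: int = 5
    scene_labels: tuple[str, ...] = SCENES
    region_labels: tuple[str, ...] = REGIONS
    scene_to_region: dict[str, str] = field(
        default_factory=lambda: dict(SCENE_TO_REGION))
    trial_seconds: float = 90.0
    baseline_seconds: float = 10.0
    fs_raw: float = 1024.0
    channel_labels: tuple[str, ...] = CHANNELS_32
    band_effects: dict[str, dict[str, float]] = field(
        default_factory=_zero_band_effects)
    band_rms: dict[str, float] = field(
        default_factory=lambda: dict(BAND_RMS_UV))
    blink_rate: float = 10.0          # events per minute
    noise_sd: float = 5.0             # pink-background RMS, microvolt
    subject_band_sd: float = 0.05     # log-normal sd of global band gain
    channel_band_sd: float = 0.10     # log-normal sd of per-channel gain
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def validate(self) -> None:
        if self.trial_seconds <= 0 or self.baseline_seconds <= 0:
            raise ValueError("durations must be positive")
        if self.fs_raw <= 0 or self.fs_raw % 128:
            raise ValueError("fs_raw must be a positive multiple of 128 Hz")
        if self.n_scenes != len(self.scene_labels):
            raise ValueError("n_scenes must match scene_labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        missing = [lab for lab in (*self.scene_labels, *self.region_labels)
                   if lab not in self.band_effects]
        if missing:
            raise ValueError(f"band_effects missing labels: {missing}")
        for scene in self.scene_labels:
            if scene not in self.scene_to_region:
                raise ValueError(f"scene {scene} lacks a region assignment")


@dataclass
class QuestionnaireConfig:
    """Generative settings for the SSQ / SAM / VRI tables."""

    ssq_severity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SSQ_SEVERITY))
    sam_centers: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SAM_CENTERS))
    vri_factor_loadings: np.ndarray = field(
        default_factory=default_vri_loadings)
    vri_general_loading: float = 0.30
    likert_levels: int = 7
    subject_gamma_shape: float = 4.0  # SSQ susceptibility heterogeneity
    sam_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        for scene, sev in self.ssq_severity.items():
            if not 0 <= sev <= 3:
                raise ValueError(f"severity for {scene} outside [0, 3]")
        for scene, c in self.sam_centers.items():
            if not all(1 <= v <= 9 for v in c):
                raise ValueError(f"SAM centers for {scene} outside [1, 9]")
        L = np.asarray(self.vri_factor_loadings)
        if L.shape[0] != 42:
            raise ValueError("VRI loading matrix must have 42 item rows")


_BLINK_SPREAD = {"Fp1": 1.0, "Fp2": 1.0, "AF3": 0.6, "AF4": 0.6,
                 "F7": 0.3, "F8": 0.3}


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int) -> np.ndarray:
    # spectral synthesis: complex Gaussian coefficients shaped by 1/sqrt(f)
    nfft = sp_fft.next_fast_len(n, real=True)
    f = np.fft.rfftfreq(nfft, d=1.0).astype(np.float32)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spec = ((rng.standard_normal((n_ch, f.size), dtype=np.float32)
             + 1j * rng.standard_normal((n_ch, f.size), dtype=np.float32))
            * scale)
    pink = sp_fft.irfft(spec, n=nfft, axis=1)[:, :n]
    pink /= pink.std(axis=1, keepdims=True)
    return pink


def _blink_template(fs: float) -> np.ndarray:
    # 400 ms biphasic pulse: one full sine cycle under a Hann envelope,
    # normalised to unit peak so the configured amplitude is the peak value.
    n = int(round(0.4 * fs))
    t = np.arange(n) / n
    w = np.sin(2 * np.pi * t) * np.hanning(n)
    return w / np.abs(w).max()


def generate_recording(cfg: SynthConfig, subject: int) -> Recording:
    """One subject's continuous recording: baseline then n_scenes trials.

    Scene order is randomised per subject.  All randomness derives from
    ``(cfg.seed, subject)``, so identical configuration and seed reproduce
    the recording bit for bit.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, subject])
    fs = cfg.fs_raw
    n_base = int(round(cfg.baseline_seconds * fs))
    n_trial = int(round(cfg.trial_seconds * fs))
    n_total = n_base + cfg.n_scenes * n_trial
    n_ch = cfg.n_channels

    order = [cfg.scene_labels[i] for i in rng.permutation(cfg.n_scenes)]

    # Subject/channel variability is specified on the band-POWER scale
    # (log-normal sd), so the amplitude multiplier is the square root.
    subj_gain = {b: np.sqrt(rng.lognormal(0.0, cfg.subject_band_sd))
                 for b in BAND_EDGES}
    chan_gain = {b: np.sqrt(np.exp(rng.normal(0.0, cfg.channel_band_sd,
                                              size=n_ch)))
                 for b in BAND_EDGES}

    data = np.float32(cfg.noise_sd) * _pink_noise(rng, n_ch, n_total)

    nfft = sp_fft.next_fast_len(n_total, real=True)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    for band, (lo, hi) in BAND_EDGES.items():
        # band-limited Gaussian noise, synthesised spectrally: complex
        # Gaussian coefficients on the in-band bins, zero elsewhere
        mask = (freqs >= lo) & (freqs < hi)
        nb = int(mask.sum())
        spec = np.zeros((n_ch, freqs.size), dtype=np.complex64)
        spec[:, mask] = (rng.standard_normal((n_ch, nb), dtype=np.float32)
                         + 1j * rng.standard_normal((n_ch, nb),
                                                    dtype=np.float32))
        comp = sp_fft.irfft(spec, n=nfft, axis=1)[:, :n_total]
        comp /= comp.std(axis=1, keepdims=True)
        base_rms = cfg.band_rms.get(band, 0.0)
        amp = np.empty(n_total, dtype=np.float32)
        amp[:n_base] = 1.0
        for i, scene in enumerate(order):
            region = cfg.scene_to_region[scene]
            offset = (cfg.band_effects[scene][band]
                      + cfg.band_effects[region][band])
            s0 = n_base + i * n_trial
            amp[s0:s0 + n_trial] = np.sqrt(max(1.0 + offset, 0.0))
        gain = (base_rms * subj_gain[band]
                * chan_gain[band][:, None]).astype(np.float32)
        data += gain * (comp * amp[None, :])

    # Blink artifacts: shared ocular source projected onto frontal channels.
    if cfg.blink_rate > 0:
        tmpl = _blink_template(fs)
        n_blinks = rng.poisson(cfg.blink_rate * n_total / fs / 60.0)
        onsets = rng.integers(0, max(n_total - len(tmpl), 1), size=n_blinks)
        source = np.zeros(n_total)
        for on in onsets:
            source[on:on + len(tmpl)] += tmpl
        amp = 10.0 * cfg.noise_sd
        for lab, w in _BLINK_SPREAD.items():
            if lab in cfg.channel_labels:
                data[cfg.channel_labels.index(lab)] += amp * w * source

    # Per-channel DC offset, removed later by baseline correction.
    data += rng.normal(0.0, 2.0, size=n_ch)[:, None]

    markers = [Marker(0.0, cfg.baseline_seconds, "baseline", "baseline",
                      subject)]
    for i, scene in enumerate(order):
        markers.append(Marker(
            onset=cfg.baseline_seconds + i * cfg.trial_seconds,
            duration=cfg.trial_seconds,
            scene=scene,
            region=cfg.scene_to_region[scene],
            subject=subject,
        ))

    return Recording(
        data=data,
        fs=fs,
        channel_labels=cfg.channel_labels,
        markers=markers,
        montage=montage_2d(cfg.channel_labels),
        reference_labels=REFERENCE_LABELS,
    )


# Standard 16-item SSQ symptom list with the overlapping item -> subscale map.
SSQ_ITEMS = (
    ("general_discomfort", ("N", "O")),
    ("fatigue", ("O",)),
    ("headache", ("O",)),
    ("eye_strain", ("O",)),
    ("difficulty_focusing", ("O", "D")),
    ("increased_salivation", ("N",)),
    ("sweating", ("N",)),
    ("nausea", ("N", "D")),
    ("difficulty_concentrating", ("N", "O")),
    ("fullness_of_head", ("D",)),
    ("blurred_vision", ("O", "D")),
    ("dizziness_eyes_open", ("D",)),
    ("dizziness_eyes_closed", ("D",)),
    ("vertigo", ("D",)),
    ("stomach_awareness", ("N",)),
    ("burping", ("N",)),
)


def generate_questionnaires(
    cfg: QuestionnaireConfig, n_subjects: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic (SSQ, SAM, VRI) tables, one row per subject x scene.

    SSQ items are Binomial(3, p) with p set by the scene severity and a
    Gamma-distributed subject susceptibility, giving integer ratings in
    {0..3} whose within-subject scene ordering mirrors the configured
    severities.  SAM ratings are rounded clipped Gaussians around the scene
    centers.  VRI responses follow an orthogonal common-factor model (7
    block factors plus one general immersion factor) discretised onto the
    7-point Likert scale.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    scenes = list(cfg.ssq_severity)

    ssq_rows, sam_rows, vri_rows = [], [], []
    L = np.asarray(cfg.vri_factor_loadings, dtype=float)
    n_items, n_fac = L.shape
    g = cfg.vri_general_loading
    noise_var = np.clip(1.0 - (L ** 2).sum(axis=1) - g ** 2, 0.05, None)

    for subj in range(n_subjects):
        suscept = rng.gamma(cfg.subject_gamma_shape,
                            1.0 / cfg.subject_gamma_shape)
        for scene in scenes:
            sev = cfg.ssq_severity[scene]
            p = float(np.clip(sev * suscept / 3.0, 0.0, 1.0))
            items = rng.binomial(3, p, size=len(SSQ_ITEMS))
            if sev == 0:
                items[:] = 0
            ssq_rows.append({"subject": subj, "scene": scene,
                             **{f"item{i + 1:02d}": int(v)
                                for i, v in enumerate(items)}})

            v, a, d = cfg.sam_centers[scene]
            vals = rng.normal([v, a, d], cfg.sam_sd)
            vals = np.clip(np.rint(vals), 1, 9).astype(int)
            sam_rows.append({"subject": subj, "scene": scene,
                             "valence": vals[0], "arousal": vals[1],
                             "dominance": vals[2]})

            F = rng.standard_normal(n_fac)
            G = rng.standard_normal()
            eps = rng.standard_normal(n_items) * np.sqrt(noise_var)
            z = L @ F + g * G + eps
            mid = (cfg.likert_levels + 1) / 2.0
            lik = np.clip(np.rint(mid + z * (cfg.likert_levels / 6.0)),
                          1, cfg.likert_levels).astype(int)
            vri_rows.append({"subject": subj, "scene": scene,
                             **{f"item{i + 1:02d}": int(v)
                                for i, v in enumerate(lik)}})

    return (pd.DataFrame(ssq_rows), pd.DataFrame(sam_rows),
            pd.DataFrame(vri_rows))
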