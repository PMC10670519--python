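"""Preprocessing chain: re-reference, resample, filter, ICA, baseline, epoch."""

import numpy as np
import pytest

from vreeg.preprocess import (
    Marker,
    Recording,
    baseline_correct,
    epoch,
    lowpass,
    preprocess_recording,
    remove_artifacts_ica,
    rereference_pair,
    resample,
)
from tests.conftest import make_epochs


def sine_recording(freq, fs=1024.0, seconds=4.0, n_ch=2):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Recording(data=data, fs=fs,
                     channel_labels=tuple(f"CH{i}" for i in range(n_ch)))


class TestRereference:
    def test_common_mode_cancels(self, rng):
        f3, f4 = rng.standard_normal((2, 100))
        cms = rng.standard_normal(100)
        rec = Recording(data=np.vstack([f3 - cms, f4 - cms]), fs=100.0,
                        channel_labels=("F3", "F4"))
        # (F3-CMS)-(F4-CMS) = F3-F4
        np.testing.assert_allclose(rereference_pair(rec, "F3", "F4"),
                                   f3 - f4, atol=1e-12)

    def test_self_difference_is_zero(self, small_recording):
        out = rereference_pair(small_recording, "Fp1", "Fp1")
        assert np.all(out == 0)

    def test_constant_offset_rejected_in_output(self, rng):
        base = rng.standard_normal((2, 50))
        rec1 = Recording(data=base, fs=50.0, channel_labels=("A", "B"))
        rec2 = Recording(data=base + 42.0, fs=50.0, channel_labels=("A", "B"))
        np.testing.assert_allclose(rereference_pair(rec1, "A", "B"),
                                   rereference_pair(rec2, "A", "B"),
                                   atol=1e-12)

    def test_unknown_channel(self, small_recording):
        with pytest.raises(KeyError):
            rereference_pair(small_recording, "Fp1", "XX")


class TestResample:
    def test_length_scaling(self):
        rec = sine_recording(10.0, fs=1024.0, seconds=460.0, n_ch=1)
        out = resample(rec, 128.0)
        assert out.data.shape[1] == 58_880  # 460 s x 128 Hz
        assert out.fs == 128.0

    def test_sine_amplitude_preserved_below_nyquist(self):
        rec = sine_recording(10.0)
        out = resample(rec, 128.0)
        # compare RMS away from the edges
        seg = out.data[0, 64:-64]
        assert np.sqrt((seg ** 2).mean()) == pytest.approx(1 / np.sqrt(2),
                                                           rel=0.01)

    def test_alias_suppression(self):
        rec = sine_recording(100.0)  # above the 64 Hz output Nyquist
        out = resample(rec, 128.0)
        in_rms = np.sqrt((rec.data[0] ** 2).mean())
        out_rms = np.sqrt((out.data[0, 64:-64] ** 2).mean())
        assert 20 * np.log10(in_rms / max(out_rms, 1e-300)) >= 40.0

    def test_upsampling_rejected(self, small_recording):
        with pytest.raises(ValueError):
            resample(small_recording, 2 * small_recording.fs)


class TestLowpass:
    def test_dc_passband_identity(self):
        rec = Recording(data=np.full((1, 1000), 3.0), fs=128.0,
                        channel_labels=("A",))
        out = lowpass(rec, 45.0)
        np.testing.assert_allclose(out.data, rec.data, rtol=1e-6)

    def test_stopband_attenuation(self):
        rec = sine_recording(60.0, fs=128.0, seconds=8.0, n_ch=1)
        out = lowpass(rec, 45.0)
        ratio = np.sqrt((out.data ** 2).mean()) / np.sqrt(
            (rec.data ** 2).mean())
        assert ratio <= 0.01

    def test_passband_preservation(self):
        rec = sine_recording(10.0, fs=128.0, seconds=8.0, n_ch=1)
        out = lowpass(rec, 45.0)
        ratio = np.sqrt((out.data ** 2).mean()) / np.sqrt(
            (rec.data ** 2).mean())
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_energy_never_increases(self, small_recording):
        out = lowpass(small_recording, 45.0)
        assert (out.data ** 2).sum() <= (small_recording.data ** 2).sum() * (
            1 + 1e-6)

    def test_cutoff_beyond_nyquist_rejected(self):
        rec = sine_recording(10.0, fs=128.0, seconds=2.0)
        with pytest.raises(ValueError):
            lowpass(rec, 70.0)


class TestEpoch:
    def test_epoch_shapes_and_labels(self, small_recording):
        eps = epoch(small_recording, window_seconds=10.0)
        assert eps.epochs.shape == (5, 32, 1280)
        assert sorted(m.scene for m in eps.labels) == sorted(
            {m.scene for m in small_recording.markers} - {"baseline"})
        assert eps.baseline_means is not None
        assert eps.baseline_means.shape == (32,)

    def test_zero_markers_gives_empty_set(self):
        rec = sine_recording(5.0, fs=128.0, seconds=5.0)
        eps = epoch(rec, window_seconds=2.0)
        assert eps.n_epochs == 0

    def test_short_trial_error_names_marker(self):
        rec = sine_recording(5.0, fs=128.0, seconds=5.0)
        rec.markers = [Marker(0.0, 2.0, "RC", "HVHA", 0)]
        with pytest.raises(ValueError, match="RC"):
            epoch(rec, window_seconds=4.0)

    def test_marker_count_conserved_through_chain(self, small_recording):
        eps, _ = preprocess_recording(small_recording, window_seconds=10.0,
                                      run_ica=False)
        n_task = sum(m.scene != "baseline" for m in small_recording.markers)
        assert eps.n_epochs == n_task


class TestBaselineCorrect:
    def test_subtracts_configured_means(self, rng):
        data = rng.standard_normal((3, 4, 100))
        bm = np.array([1.0, -2.0, 0.5, 10.0])
        eps = make_epochs(data, fs=10.0, baseline=bm)
        out = baseline_correct(eps)
        np.testing.assert_allclose(out.epochs, data - bm[None, :, None])

    def test_zero_baseline_is_identity_and_idempotent(self, rng):
        data = rng.standard_normal((2, 3, 50))
        eps = make_epochs(data, fs=10.0, baseline=np.zeros(3))
        out = baseline_correct(eps)
        np.testing.assert_allclose(out.epochs, data)
        again = baseline_correct(out)  # corrected set has zero baseline
        np.testing.assert_allclose(again.epochs, out.epochs)

    def test_missing_baseline_rejected(self, rng):
        eps = make_epochs(rng.standard_normal((2, 3, 50)), fs=10.0)
        with pytest.raises(ValueError):
            baseline_correct(eps)


class TestICA:
    @pytest.fixture
    def blinky_epochs(self, rng):
        """Mixed noise sources plus one planted blink source."""
        n_trials, n_ch, n_samp = 4, 6, 1280
        fs = 128.0
        sources = rng.standard_normal((n_ch - 1, n_trials * n_samp))
        blink = np.zeros(n_trials * n_samp)
        tmpl = np.sin(2 * np.pi * np.arange(51) / 51) * np.hanning(51)
        for on in rng.integers(0, n_trials * n_samp - 51, size=40):
            blink[on:on + 51] += tmpl
        blink *= 30.0
        mix = rng.standard_normal((n_ch, n_ch - 1))
        data = mix @ sources
        blink_weights = np.array([1.0, 1.0, 0.3, 0.1, 0.0, 0.0])
        data += np.outer(blink_weights, blink)
        eps_data = data.reshape(n_ch, n_trials, n_samp).transpose(1, 0, 2)
        eps = make_epochs(eps_data, fs=fs)
        eps.channel_labels = ("Fp1", "Fp2", "AF3", "AF4", "Cz", "Pz")
        return eps, blink

    def test_planted_blink_removed(self, blinky_epochs):
        eps, blink = blinky_epochs
        cleaned, rep = remove_artifacts_ica(
            eps, frontal_channels=("Fp1", "Fp2"), corr_threshold=0.7, seed=0)
        assert len(rep.removed) == 1
        # frontal RMS during blink activity drops by at least half
        fr = eps.epochs[:, 0, :].ravel()
        fr_clean = cleaned.epochs[:, 0, :].ravel()
        active = np.abs(blink) > 5.0
        before = np.sqrt((fr[active] ** 2).mean())
        after = np.sqrt((fr_clean[active] ** 2).mean())
        assert after <= 0.5 * before

    def test_no_removal_without_blinks(self, rng):
        data = rng.standard_normal((3, 5, 640))
        eps = make_epochs(data, fs=128.0)
        eps.channel_labels = ("Fp1", "Fp2", "C3", "C4", "Pz")
        _, rep = remove_artifacts_ica(eps, frontal_channels=("Fp1", "Fp2"),
                                      corr_threshold=0.7, seed=0)
        assert rep.removed == []

    def test_unattainable_threshold_is_identity(self, blinky_epochs):
        eps, _ = blinky_epochs
        cleaned, rep = remove_artifacts_ica(
            eps, frontal_channels=("Fp1", "Fp2"), corr_threshold=1.0, seed=0)
        assert rep.removed == []
        np.testing.assert_allclose(cleaned.epochs, eps.epochs, atol=1e-6)

    def test_energy_never_increases(self, blinky_epochs):
        eps, _ = blinky_epochs
        cleaned, rep = remove_artifacts_ica(
            eps, frontal_channels=("Fp1", "Fp2"), corr_threshold=0.7, seed=0)
        assert rep.removed  # something was removed
        assert (cleaned.epochs ** 2).sum() <= (eps.epochs ** 2).sum() * (
            1 + 1e-9)
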