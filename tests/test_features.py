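"""qEEG feature extraction: Welch PSD, band powers, spectral entropy,
coherence, PAC modulation index, and feature-vector assembly."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps
from scipy.signal import hilbert

from qeegml import CHANNELS_1020, EEGRecording, channel_pairs
from qeegml.features import (
    FeatureExtractionError,
    N_PHASE_BINS,
    SpectrumEstimate,
    assemble_feature_vector,
    band_power_features,
    broadband_coherence,
    coherence_features,
    coherence_spectra,
    extract_features,
    feature_names,
    modulation_index,
    pac_mi,
    phase_amplitude_histogram,
    spectral_entropy,
    welch_spectrum,
)
from qeegml.filters import spectral_noise

FS = 250.0


def _sine(freq, duration=180.0, amp=1.0, fs=FS, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestWelchSpectrum:
    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(int(180 * FS))
        spec = welch_spectrum(x, FS)
        total = spec.psd.sum() * spec.df
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_sine_power_concentrated(self):
        amp = 3.0
        spec = welch_spectrum(_sine(10, amp=amp), FS)
        total = spec.psd.sum() * spec.df
        assert total == pytest.approx(amp**2 / 2, rel=0.05)
        peak = spec.frequencies[np.argmax(spec.psd)]
        assert peak == pytest.approx(10.0, abs=spec.df)
        # >= 99% of the mass within +-1 Hz of the tone
        near = np.abs(spec.frequencies - 10.0) <= 1.0
        assert spec.psd[near].sum() / spec.psd.sum() > 0.99

    def test_zero_signal_zero_spectrum(self):
        spec = welch_spectrum(np.zeros(int(10 * FS)), FS)
        assert np.all(spec.psd == 0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(FeatureExtractionError):
            welch_spectrum(np.zeros(100), FS)


class TestBandPower:
    def test_pure_alpha_sine(self):
        rec = EEGRecording(channel_labels=["CZ"], fs=FS, data=_sine(10)[None, :])
        _, rel = band_power_features(rec)
        assert rel["relPSD:CZ:alpha"] == pytest.approx(1.0, abs=0.02)
        for b in ("delta", "theta", "mu", "beta", "gamma"):
            assert rel[f"relPSD:CZ:{b}"] < 0.02

    def test_white_noise_proportional_to_bandwidth(self, rng):
        x = rng.standard_normal(int(180 * FS))
        rec = EEGRecording(channel_labels=["CZ"], fs=FS, data=x[None, :])
        _, rel = band_power_features(rec)
        # flat spectrum: delta fraction ~ 3 Hz / 99 Hz
        assert rel["relPSD:CZ:delta"] == pytest.approx(3 / 99, rel=0.15)

    def test_relative_values_bounded(self, rng):
        x = spectral_noise(rng, 1, int(180 * FS), FS, 1.0, 100.0)
        rec = EEGRecording(channel_labels=["CZ"], fs=FS, data=x)
        _, rel = band_power_features(rec)
        vals = np.array(list(rel.values()))
        assert np.all((vals >= 0) & (vals <= 1))
        assert vals.sum() <= 1.0 + 1e-9  # six bands do not tile 1-100 Hz

    def test_zero_power_flags_subject(self):
        rec = EEGRecording(channel_labels=["CZ"], fs=FS, data=np.zeros((1, int(10 * FS))))
        with pytest.raises(FeatureExtractionError):
            band_power_features(rec)


class TestSpectralEntropy:
    def test_single_bin_zero(self):
        f = np.arange(1, 101, dtype=float)
        psd = np.zeros(100)
        psd[40] = 5.0
        spec = SpectrumEstimate(f, psd, "hamming", 500, 250)
        assert spectral_entropy(spec) == 0.0

    def test_uniform_is_log2_n(self):
        f = np.arange(1, 101, dtype=float)
        spec = SpectrumEstimate(f, np.ones(100), "hamming", 500, 250)
        assert spectral_entropy(spec) == pytest.approx(np.log2(100))

    def test_white_noise_near_maximum(self, rng):
        x = rng.standard_normal(int(180 * FS))
        spec = welch_spectrum(x, FS)
        n_bins = int(np.sum((spec.frequencies >= 1) & (spec.frequencies <= 100)))
        h = spectral_entropy(spec)
        assert h == pytest.approx(np.log2(n_bins), rel=0.05)
        assert h <= np.log2(n_bins)

    def test_all_zero_rejected(self):
        f = np.arange(1, 11, dtype=float)
        spec = SpectrumEstimate(f, np.zeros(10), "hamming", 500, 250)
        with pytest.raises(FeatureExtractionError):
            spectral_entropy(spec)


class TestCoherence:
    def test_copied_channel_coherence_one(self, rng):
        x = spectral_noise(rng, 1, int(180 * FS), FS, 1.0, 100.0)[0]
        rec = EEGRecording(channel_labels=["A", "B"], fs=FS, data=np.vstack([x, x]))
        coh = coherence_features(rec)
        for v in coh.values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_shared_source_matches_analytic_value(self, rng):
        """x = s + n1, y = s + n2 at SNR 1: MSC = (SNR/(1+SNR))^2 = 0.25."""
        n = int(600 * FS)  # 20 epochs -> small estimator bias
        s = spectral_noise(rng, 1, n, FS, 1.0, 40.0)[0]
        n1 = spectral_noise(rng, 1, n, FS, 1.0, 40.0)[0]
        n2 = spectral_noise(rng, 1, n, FS, 1.0, 40.0)[0]
        rec = EEGRecording(channel_labels=["A", "B"], fs=FS, data=np.vstack([s + n1, s + n2]))
        freqs, coh = coherence_spectra(rec)
        band = (freqs >= 5) & (freqs <= 35)
        assert coh[0, band].mean() == pytest.approx(0.25, abs=0.05)

    def test_matches_scipy_estimator(self, rng):
        """Vectorized epoch-FFT estimator equals scipy.signal.coherence with
        the same window/segmentation (independent implementation)."""
        x = rng.standard_normal((2, int(180 * FS)))
        rec = EEGRecording(channel_labels=["A", "B"], fs=FS, data=x)
        freqs, coh = coherence_spectra(rec)
        f_sp, c_sp = sps.coherence(
            x[0], x[1], fs=FS, window="hamming", nperseg=int(30 * FS), noverlap=0
        )
        np.testing.assert_allclose(freqs, f_sp)
        np.testing.assert_allclose(coh[0], c_sp, atol=1e-10)

    def test_census_and_bounds(self, rng):
        x = rng.standard_normal((19, int(180 * FS)))
        rec = EEGRecording(channel_labels=list(CHANNELS_1020), fs=FS, data=x)
        coh = coherence_features(rec)
        assert len(coh) == 171 * 6
        vals = np.array(list(coh.values()))
        assert np.all((vals >= 0) & (vals <= 1))
        bb = broadband_coherence(rec)
        assert len(bb) == 171

    def test_too_few_epochs_rejected(self, rng):
        rec = EEGRecording(
            channel_labels=["A", "B"], fs=FS, data=rng.standard_normal((2, int(45 * FS)))
        )
        with pytest.raises(FeatureExtractionError):
            coherence_features(rec)


class TestPacMi:
    def test_uniform_distribution_zero(self):
        assert modulation_index(np.full(N_PHASE_BINS, 1 / N_PHASE_BINS)) == 0.0

    def test_single_bin_is_one(self):
        P = np.zeros(N_PHASE_BINS)
        P[4] = 1.0
        assert modulation_index(P) == pytest.approx(1.0)

    def test_constant_amplitude_zero(self):
        phase_sig = _sine(10, duration=60)
        amp_sig = _sine(30, duration=60)  # constant envelope
        assert pac_mi(phase_sig, amp_sig) == pytest.approx(0.0, abs=1e-3)

    def test_constructed_coupling_matches_histogram_oracle(self, rng):
        """Sinusoidally modulated gamma: MI from the pipeline equals a
        brute-force histogram computed from the known phase and envelope."""
        d = 0.5
        n = int(180 * FS)
        alpha = spectral_noise(rng, 1, n, FS, 8.0, 12.0)[0]
        gamma = spectral_noise(rng, 1, n, FS, 25.0, 40.0)[0]
        phi = np.angle(hilbert(alpha))
        coupled = gamma * (1 + d * np.cos(phi))
        mi = pac_mi(alpha, coupled)
        # oracle: bin the known envelope |hilbert(gamma)| * (1 + d cos phi)
        env_known = np.abs(hilbert(gamma)) * (1 + d * np.cos(phi))
        edges = np.linspace(-np.pi, np.pi, N_PHASE_BINS + 1)
        idx = np.clip(np.digitize(phi, edges) - 1, 0, N_PHASE_BINS - 1)
        means = np.array([env_known[idx == j].mean() for j in range(N_PHASE_BINS)])
        P = means / means.sum()
        mi_oracle = float((P[P > 0] * np.log(P[P > 0] * N_PHASE_BINS)).sum() / np.log(N_PHASE_BINS))
        assert mi == pytest.approx(mi_oracle, rel=0.15)
        # and both agree with the analytic small-d value d^2/4/ln(18)
        assert mi_oracle == pytest.approx(d**2 / 4 / np.log(18), rel=0.2)

    def test_phase_shuffled_surrogate_collapses(self, rng):
        d = 0.8
        n = int(180 * FS)
        alpha = spectral_noise(rng, 1, n, FS, 8.0, 12.0)[0]
        gamma = spectral_noise(rng, 1, n, FS, 25.0, 40.0)[0]
        phi = np.angle(hilbert(alpha))
        coupled = gamma * (1 + d * np.cos(phi))
        mi = pac_mi(alpha, coupled)
        surrogates = [
            pac_mi(np.roll(alpha, int(shift)), coupled)
            for shift in rng.integers(int(5 * FS), n - int(5 * FS), size=5)
        ]
        assert np.max(surrogates) < mi / 5


class TestAssembly:
    def test_census_1330_and_1333(self):
        assert len(feature_names()) == 1330
        assert len(feature_names(include_demo=True)) == 1333
        cats = {}
        for name in feature_names():
            cats[name.split(":")[0]] = cats.get(name.split(":")[0], 0) + 1
        assert cats == {"absPSD": 114, "relPSD": 114, "Coh": 1026, "SE": 19, "PAC": 57}
        assert len(channel_pairs()) == 171

    def test_input_order_irrelevant(self, rng):
        names = feature_names()
        values = {n: float(v) for n, v in zip(names, rng.standard_normal(len(names)))}
        shuffled = dict(sorted(values.items(), key=lambda kv: kv[1]))
        a = assemble_feature_vector(values)
        b = assemble_feature_vector(shuffled)
        assert a.equals(b)
        assert list(a.index) == names

    def test_missing_and_nonfinite_rejected(self, rng):
        names = feature_names()
        values = {n: 1.0 for n in names}
        values.pop("SE:CZ")
        with pytest.raises(FeatureExtractionError, match="missing"):
            assemble_feature_vector(values)
        values["SE:CZ"] = np.nan
        with pytest.raises(FeatureExtractionError, match="non-finite"):
            assemble_feature_vector(values)

    def test_demographics_block(self):
        values = {n: 1.0 for n in feature_names()}
        demo = {"sex": "F", "age": 44.0, "medication": 3}
        vec = assemble_feature_vector(values, demo, include_demo=True)
        assert len(vec) == 1333
        assert vec["demo:sex"] == 1.0
        assert vec["demo:age"] == 44.0

    def test_extraction_deterministic(self, rng):
        x = rng.standard_normal((19, int(180 * FS)))
        rec = EEGRecording(
            channel_labels=list(CHANNELS_1020), fs=FS, data=x,
            demographics={"sex": "M", "age": 30.0, "medication": 0},
        )
        a = extract_features(rec, include_demo=True)
        b = extract_features(rec, include_demo=True)
        assert a.equals(b)
        assert len(a) == 1333
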