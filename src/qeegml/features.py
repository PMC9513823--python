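"""qEEG feature extraction: the deterministic 1330-entry feature vector.

Feature census for the 19-channel montage and six bands:

================  ==========================  =====
category          index                       count
================  ==========================  =====
absPSD            channel x band              114
relPSD            channel x band              114
Coh               channel pair x band         1026
SE                channel                     19
PAC               channel x band pairing      57
================  ==========================  =====
total                                         1330

With the optional demographic block (sex, age, medication): 1333.

Estimator choices: Welch PSD with 2-s Hamming segments at 50% overlap;
magnitude-squared coherence averaged over 30-s non-overlapping epochs;
spectral entropy over the 1-100 Hz bins in bits; PAC modulation index with
18 phase bins and natural-log KL normalization (MI in [0, 1]).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.signal import hilbert

from .bands import DEFAULT_BANDS, PAC_PAIRINGS, BandScheme
from .filters import design_bandpass, filtfilt_fir
from .montage import CHANNELS_1020, channel_pairs
from .recording import EEGRecording

CATEGORIES = ("absPSD", "relPSD", "Coh", "SE", "PAC")
DEMO_FEATURES = ("demo:sex", "demo:age", "demo:medication")
SEX_CODES = {"M": 0.0, "F": 1.0, "U": 2.0}
SCHEMA_VERSION = "qeegml-features-1"


class FeatureExtractionError(ValueError):
    pass


# --- schema -------------------------------------------------------------------

def feature_names(
    bands: BandScheme = DEFAULT_BANDS,
    channels: Sequence[str] = CHANNELS_1020,
    include_demo: bool = False,
) -> list[str]:
    """Canonical ordered feature names ("category:channel[-pair][:band]")."""
    names: list[str] = []
    band_names = bands.names
    for ch in channels:
        for b in band_names:
            names.append(f"absPSD:{ch}:{b}")
    for ch in channels:
        for b in band_names:
            names.append(f"relPSD:{ch}:{b}")
    for a, c in channel_pairs(tuple(channels)):
        for b in band_names:
            names.append(f"Coh:{a}-{c}:{b}")
    for ch in channels:
        names.append(f"SE:{ch}")
    for ch in channels:
        for lo_b, hi_b in PAC_PAIRINGS:
            names.append(f"PAC:{ch}:{lo_b}-{hi_b}")
    if include_demo:
        names.extend(DEMO_FEATURES)
    return names


def feature_category(name: str) -> str:
    return name.split(":", 1)[0]


def schema_hash(columns: Iterable[str]) -> str:
    h = hashlib.md5()
    for c in columns:
        h.update(c.encode())
        h.update(b"\x00")
    return h.hexdigest()


# --- spectrum -----------------------------------------------------------------

@dataclass
class SpectrumEstimate:
    """Welch power spectral density (uV^2/Hz) with estimator metadata."""

    frequencies: np.ndarray
    psd: np.ndarray
    window: str
    nperseg: int
    noverlap: int

    def __post_init__(self) -> None:
        if np.any(self.psd < -1e-12):
            raise ValueError("power values must be non-negative")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def band_power(self, lo: float, hi: float, closed: bool = False) -> float:
        """Integrated power over ``[lo, hi)`` (or ``[lo, hi]`` if closed)."""
        f = self.frequencies
        mask = (f >= lo) & ((f <= hi) if closed else (f < hi))
        return float(self.psd[mask].sum() * self.df)


def welch_spectrum(
    x: np.ndarray,
    fs: float,
    seg_seconds: float = 2.0,
    overlap: float = 0.5,
    window: str = "hamming",
) -> SpectrumEstimate:
    """Modified-periodogram (Welch) average; Parseval-consistent with the
    signal variance when integrated over [0, fs/2]."""
    nperseg = int(round(seg_seconds * fs))
    if len(x) < nperseg:
        raise FeatureExtractionError(
            f"signal of {len(x)} samples shorter than one {seg_seconds} s segment"
        )
    noverlap = int(round(nperseg * overlap))
    f, p = signal.welch(x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)
    return SpectrumEstimate(frequencies=f, psd=p, window=window,
                            nperseg=nperseg, noverlap=noverlap)


def band_power_features(
    rec: EEGRecording, bands: BandScheme = DEFAULT_BANDS
) -> tuple[dict[str, float], dict[str, float]]:
    """Absolute and relative band power per channel.

    Relative power divides by the total over the closed 1-100 Hz interval.
    A channel with zero total power raises :class:`FeatureExtractionError`
    (the subject must be flagged upstream, NaNs are never emitted).
    """
    abs_feats: dict[str, float] = {}
    rel_feats: dict[str, float] = {}
    for i, ch in enumerate(rec.channel_labels):
        spec = welch_spectrum(rec.data[i], rec.fs)
        total = spec.band_power(*bands.total, closed=True)
        if total <= 0:
            raise FeatureExtractionError(f"channel {ch}: zero total power")
        for name, lo, hi in bands.bands:
            p = spec.band_power(lo, hi)
            abs_feats[f"absPSD:{ch}:{name}"] = p
            rel_feats[f"relPSD:{ch}:{name}"] = p / total
    return abs_feats, rel_feats


def spectral_entropy(
    spectrum: SpectrumEstimate, domain: tuple[float, float] = (1.0, 100.0)
) -> float:
    """Shannon entropy (bits) of the normalized spectrum over ``domain``.

    Zero-power bins contribute nothing; the value lies in
    ``[0, log2(n_bins)]``.
    """
    f = spectrum.frequencies
    mask = (f >= domain[0]) & (f <= domain[1])
    s = spectrum.psd[mask]
    total = s.sum()
    if total <= 0:
        raise FeatureExtractionError("all-zero spectrum in entropy domain")
    p = s / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def entropy_features(rec: EEGRecording, bands: BandScheme = DEFAULT_BANDS) -> dict[str, float]:
    return {
        f"SE:{ch}": spectral_entropy(welch_spectrum(rec.data[i], rec.fs), bands.total)
        for i, ch in enumerate(rec.channel_labels)
    }


# --- coherence ----------------------------------------------------------------

def coherence_spectra(
    rec: EEGRecording, epoch_seconds: float = 30.0, window: str = "hamming"
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence for all channel pairs at once.

    Segments the recording into non-overlapping ``epoch_seconds`` epochs
    (Welch/mscohere convention with zero overlap), returns
    ``(frequencies, coh)`` where ``coh`` has shape ``(n_pairs, n_freqs)``
    and pair order is the canonical upper triangle.
    """
    n_ch, n = rec.data.shape
    nper = int(round(epoch_seconds * rec.fs))
    n_ep = n // nper
    if n_ep < 2:
        raise FeatureExtractionError(
            f"need >= 2 epochs of {epoch_seconds} s; recording has {rec.duration:.0f} s"
        )
    win = signal.get_window(window, nper)
    segs = rec.data[:, : n_ep * nper].reshape(n_ch, n_ep, nper)
    segs = segs - segs.mean(axis=-1, keepdims=True)  # per-segment detrend
    F = np.fft.rfft(segs * win, axis=-1)  # (ch, epoch, freq)
    freqs = np.fft.rfftfreq(nper, d=1.0 / rec.fs)
    auto = (F * F.conj()).real.mean(axis=1)  # (ch, freq)
    iu, ju = np.triu_indices(n_ch, k=1)
    cross = (F[iu] * F[ju].conj()).mean(axis=1)  # (pairs, freq)
    denom = auto[iu] * auto[ju]
    coh = np.zeros_like(denom)
    ok = denom > 0
    coh[ok] = (np.abs(cross) ** 2)[ok] / denom[ok]
    return freqs, coh


def coherence_features(
    rec: EEGRecording, bands: BandScheme = DEFAULT_BANDS, epoch_seconds: float = 30.0
) -> dict[str, float]:
    """Per-pair, per-band mean magnitude-squared coherence (1026 values)."""
    freqs, coh = coherence_spectra(rec, epoch_seconds)
    pairs = channel_pairs(tuple(rec.channel_labels))
    feats: dict[str, float] = {}
    for name, lo, hi in bands.bands:
        mask = (freqs >= lo) & (freqs < hi)
        vals = coh[:, mask].mean(axis=1)
        for (a, c), v in zip(pairs, vals):
            feats[f"Coh:{a}-{c}:{name}"] = float(v)
    return feats


def broadband_coherence(
    rec: EEGRecording,
    interval: tuple[float, float] = (1.0, 40.0),
    epoch_seconds: float = 30.0,
) -> dict[str, float]:
    """Mean coherence over the broadband interval per pair (contrast maps)."""
    freqs, coh = coherence_spectra(rec, epoch_seconds)
    mask = (freqs >= interval[0]) & (freqs <= interval[1])
    pairs = channel_pairs(tuple(rec.channel_labels))
    vals = coh[:, mask].mean(axis=1)
    return {f"bbCoh:{a}-{c}": float(v) for (a, c), v in zip(pairs, vals)}


# --- phase-amplitude coupling ---------------------------------------------------

N_PHASE_BINS = 18


def phase_amplitude_histogram(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = N_PHASE_BINS
) -> np.ndarray:
    """Mean amplitude per phase bin over [-pi, pi), normalized to sum 1."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = means.sum()
    if total <= 0:
        return np.full(n_bins, 1.0 / n_bins)
    return means / total


def modulation_index(P: np.ndarray) -> float:
    """KL divergence of P from uniform, normalized by ln(n_bins); in [0, 1]."""
    n = len(P)
    nz = P > 0
    dkl = float((P[nz] * np.log(P[nz] * n)).sum())
    return dkl / np.log(n)


def pac_mi(
    phase_signal: np.ndarray, amp_signal: np.ndarray, n_bins: int = N_PHASE_BINS
) -> float:
    """Modulation index between a phase-band and an amplitude-band signal.

    The instantaneous phase of the lower band and amplitude envelope of the
    higher band come from the analytic signal; a phase-independent envelope
    yields MI = 0.
    """
    phase = np.angle(hilbert(phase_signal))
    amp = np.abs(hilbert(amp_signal))
    return modulation_index(phase_amplitude_histogram(phase, amp, n_bins))


def pac_features(rec: EEGRecording, bands: BandScheme = DEFAULT_BANDS) -> dict[str, float]:
    """MI for the three band pairings per channel (57 values).

    The lower-frequency band of each pairing supplies the phase; PAC is
    computed on the whole segment (no epoching).
    """
    needed = sorted({b for pair in PAC_PAIRINGS for b in pair})
    filtered: dict[str, np.ndarray] = {}
    for name in needed:
        lo, hi = bands.interval(name)
        taps = design_bandpass(rec.fs, lo, hi)
        filtered[name] = filtfilt_fir(taps, rec.data, axis=1)
    feats: dict[str, float] = {}
    for i, ch in enumerate(rec.channel_labels):
        for lo_b, hi_b in PAC_PAIRINGS:
            feats[f"PAC:{ch}:{lo_b}-{hi_b}"] = pac_mi(filtered[lo_b][i], filtered[hi_b][i])
    return feats


# --- assembly -------------------------------------------------------------------

def assemble_feature_vector(
    features: dict[str, float],
    demographics: dict | None = None,
    include_demo: bool = False,
    bands: BandScheme = DEFAULT_BANDS,
    channels: Sequence[str] = CHANNELS_1020,
) -> pd.Series:
    """Order computed features into the canonical fixed-length vector.

    Missing entries or NaNs are rejected; input ordering is irrelevant.
    """
    names = feature_names(bands, channels, include_demo=False)
    missing = [n for n in names if n not in features]
    if missing:
        raise FeatureExtractionError(
            f"{len(missing)} features missing (first: {missing[0]})"
        )
    values = np.array([features[n] for n in names], dtype=float)
    if np.any(~np.isfinite(values)):
        bad = names[int(np.flatnonzero(~np.isfinite(values))[0])]
        raise FeatureExtractionError(f"non-finite feature value at {bad}")
    out = pd.Series(values, index=names)
    if include_demo:
        if demographics is None:
            raise FeatureExtractionError("include_demo=True but no demographics given")
        sex = demographics["sex"]
        demo = pd.Series(
            {
                "demo:sex": SEX_CODES[sex] if isinstance(sex, str) else float(sex),
                "demo:age": float(demographics["age"]),
                "demo:medication": float(demographics["medication"]),
            }
        )
        if demo.isna().any():
            raise FeatureExtractionError("non-finite demographic value")
        out = pd.concat([out, demo[list(DEMO_FEATURES)]])
    return out


def extract_features(
    rec: EEGRecording,
    bands: BandScheme = DEFAULT_BANDS,
    include_demo: bool = False,
) -> pd.Series:
    """Compute the full feature vector (1330, or 1333 with demographics)."""
    feats: dict[str, float] = {}
    a, r = band_power_features(rec, bands)
    feats.update(a)
    feats.update(r)
    feats.update(coherence_features(rec, bands))
    feats.update(entropy_features(rec, bands))
    feats.update(pac_features(rec, bands))
    return assemble_feature_vector(
        feats, rec.demographics if include_demo else None, include_demo, bands,
        rec.channel_labels,
    )


def build_feature_table(
    recs: Iterable[EEGRecording],
    bands: BandScheme = DEFAULT_BANDS,
    include_demo: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature table (subjects x features) plus the class-label series."""
    rows, labels, ids = [], [], []
    for rec in recs:
        rows.append(extract_features(rec, bands, include_demo))
        labels.append(rec.class_label)
        ids.append(rec.subject_id)
    table = pd.DataFrame(rows, index=ids)
    return table, pd.Series(labels, index=ids, name="class")
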