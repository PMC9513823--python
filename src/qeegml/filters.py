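"""Windowed-sinc FIR design and zero-phase application helpers shared by
preprocessing, feature extraction and the synthetic generator.

Design rule (analysis filters): Hamming window; lower transition width = 25%
of the lower band edge, upper transition width = min(25% of the upper edge,
5 Hz); -6 dB cutoffs sit mid-transition. A symmetric odd-length (type-I)
FIR applied with centred convolution is exactly zero-phase, so filtering
commutes with time reversal; edges are reflection-padded to suppress
transients. Application runs in the frequency domain (overlap-free FFT
convolution), which keeps multi-thousand-tap filters cheap.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal

#: Hamming-window normalized transition width (Harris): numtaps ~ 3.3 / (dF/fs)
_HAMMING_TW = 3.3


@lru_cache(maxsize=128)
def design_bandpass(
    fs: float,
    lo: float,
    hi: float,
    lo_trans: float | None = None,
    hi_trans: float | None = None,
    inward: bool = False,
) -> np.ndarray:
    """Linear-phase FIR bandpass taps for passband ``[lo, hi]`` Hz.

    With ``inward=True`` the transition bands lie inside ``[lo, hi]`` so the
    output energy is confined to the interval (used by the synthetic
    generator); otherwise they straddle the edges (analysis convention).
    """
    if not (0 < lo < hi):
        raise ValueError(f"invalid band edges ({lo}, {hi})")
    if hi >= fs / 2:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist {fs / 2} Hz")
    if lo_trans is None:
        lo_trans = 0.25 * lo
    if hi_trans is None:
        hi_trans = min(0.25 * hi, 5.0)
    if inward:
        f1 = lo + lo_trans / 2.0
        f2 = hi - hi_trans / 2.0
        if f1 >= f2:
            raise ValueError("band too narrow for inward transitions")
    else:
        f1 = lo - lo_trans / 2.0
        f2 = min(hi + hi_trans / 2.0, fs / 2 * 0.999)
    if f1 <= 0:
        raise ValueError("lower transition extends below 0 Hz")
    width = min(lo_trans, hi_trans)
    numtaps = int(np.ceil(_HAMMING_TW * fs / width))
    numtaps += 1 - numtaps % 2  # force odd (type-I, zero-phase when centred)
    return signal.firwin(numtaps, [f1, f2], pass_zero=False, window="hamming", fs=fs)


def filtfilt_fir(taps: np.ndarray, data: np.ndarray, axis: int = -1) -> np.ndarray:
    """Zero-phase application of a symmetric FIR via centred FFT convolution.

    Edges are reflection-padded by half the filter length.
    """
    data = np.asarray(data, dtype=float)
    if axis != -1 and axis != data.ndim - 1:
        data = np.moveaxis(data, axis, -1)
        out = filtfilt_fir(taps, data, axis=-1)
        return np.moveaxis(out, -1, axis)
    half = len(taps) // 2
    pad = min(half, data.shape[-1] - 1)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    kernel = taps.reshape((1,) * (data.ndim - 1) + (-1,))
    out = signal.fftconvolve(padded, kernel, mode="same", axes=-1)
    return out[..., pad:-pad] if pad else out


def raised_cosine_band_gain(
    freqs: np.ndarray, lo: float, hi: float, trans: float = 0.5
) -> np.ndarray:
    """Spectral gain mask: 1 inside ``[lo+trans, hi-trans]``, raised-cosine
    ramps over the inward transition bands, 0 outside ``[lo, hi]``."""
    tw = min(trans, (hi - lo) / 4.0)
    g = np.zeros_like(freqs)
    g[(freqs >= lo + tw) & (freqs <= hi - tw)] = 1.0
    rise = (freqs >= lo) & (freqs < lo + tw)
    g[rise] = 0.5 * (1 - np.cos(np.pi * (freqs[rise] - lo) / tw))
    fall = (freqs > hi - tw) & (freqs <= hi)
    g[fall] = 0.5 * (1 - np.cos(np.pi * (hi - freqs[fall]) / tw))
    return g


def spectral_noise(
    rng: np.random.Generator,
    n_rows: int,
    n_samples: int,
    fs: float,
    lo: float,
    hi: float,
    trans: float = 0.5,
    analytic: bool = False,
) -> np.ndarray:
    """Unit-variance Gaussian noise with a raised-cosine band-limited spectrum.

    Synthesized directly in the frequency domain (equivalent in distribution
    to ideally band-filtered white noise). With ``analytic=True`` the complex
    analytic signal is returned (real part = signal, angle = instantaneous
    phase), saving a Hilbert transform downstream.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = raised_cosine_band_gain(freqs, lo, hi, trans)
    nz = np.flatnonzero(gain)
    spec = np.zeros((n_rows, len(freqs)), dtype=complex)
    z = rng.standard_normal((n_rows, len(nz))) + 1j * rng.standard_normal((n_rows, len(nz)))
    spec[:, nz] = z * gain[nz]
    if analytic:
        full = np.zeros((n_rows, n_samples), dtype=complex)
        full[:, : len(freqs)] = 2.0 * spec
        full[:, 0] *= 0.5
        if n_samples % 2 == 0:
            full[:, len(freqs) - 1] *= 0.5
        out = np.fft.ifft(full, axis=-1)
        real = out.real
    else:
        out = np.fft.irfft(spec, n=n_samples, axis=-1)
        real = out
    real_c = real - real.mean(axis=-1, keepdims=True)
    sd = real_c.std(axis=-1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    if analytic:
        return (out - out.real.mean(axis=-1, keepdims=True)) / sd
    return real_c / sd


def bandlimited_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fs: float,
    lo: float,
    hi: float,
    trans: float = 0.5,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``[lo, hi]`` Hz.

    Transitions lie inside the interval (width ``trans`` Hz, shrunk for
    narrow bands) so virtually all output power falls in ``[lo, hi]``;
    rows are re-standardized to zero mean / unit variance.
    """
    tw = min(trans, (hi - lo) / 4.0)
    taps = design_bandpass(fs, lo, hi, lo_trans=tw, hi_trans=tw, inward=True)
    white = rng.standard_normal(shape)
    kernel = taps.reshape((1,) * (white.ndim - 1) + (-1,))
    out = signal.fftconvolve(white, kernel, mode="same", axes=-1)
    out -= out.mean(axis=-1, keepdims=True)
    sd = out.std(axis=-1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return out / sd
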