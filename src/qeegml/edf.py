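"""EDF (European Data Format) I/O.

Writing uses a minimal in-package EDF encoder (16-bit, 1-second data
records, physical units uV); reading goes through :mod:`mne`. The writer
covers exactly what the synthetic cohort needs: integer sampling rates and
whole-second durations. Round-trip error is bounded by the 16-bit
quantization step of each channel's physical range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import EEGRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def quantization_step(phys_min: float, phys_max: float) -> float:
    return (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a plain EDF file (not EDF+)."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records * fs != rec.n_samples:
        raise ValueError("EDF writer requires a whole number of 1 s records")
    n_ch = rec.n_channels

    phys_min, phys_max = [], []
    digital = np.empty((n_ch, rec.n_samples), dtype="<i2")
    for c in range(n_ch):
        span = float(np.max(np.abs(rec.data[c]))) * 1.0001 + 1e-6
        span = float(f"{span:.6g}")
        pmin, pmax = -span, span
        phys_min.append(pmin)
        phys_max.append(pmax)
        scaled = (rec.data[c] - pmin) / (pmax - pmin) * (_DIG_MAX - _DIG_MIN) + _DIG_MIN
        digital[c] = np.clip(np.round(scaled), _DIG_MIN, _DIG_MAX).astype("<i2")

    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii(rec.subject_id or "X", 80)
    header += _ascii(f"class={rec.class_label or 'NA'}", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(str(256 * (n_ch + 1)), 8)
    header += _ascii("", 44)
    header += _ascii(str(n_records), 8)
    header += _ascii("1", 8)  # record duration, seconds
    header += _ascii(str(n_ch), 4)
    for label in rec.channel_labels:
        header += _ascii(label, 16)
    for _ in range(n_ch):
        header += _ascii("", 80)           # transducer
    for _ in range(n_ch):
        header += _ascii("uV", 8)          # physical dimension
    for v in phys_min:
        header += _ascii(f"{v:.6g}", 8)
    for v in phys_max:
        header += _ascii(f"{v:.6g}", 8)
    for _ in range(n_ch):
        header += _ascii(str(_DIG_MIN), 8)
    for _ in range(n_ch):
        header += _ascii(str(_DIG_MAX), 8)
    for _ in range(n_ch):
        header += _ascii("", 80)           # prefiltering
    for _ in range(n_ch):
        header += _ascii(str(fs), 8)       # samples per record
    for _ in range(n_ch):
        header += _ascii("", 32)
    assert len(header) == 256 * (n_ch + 1)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (uV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne loads volts
    labels = [ch.upper() for ch in raw.ch_names]
    return EEGRecording(
        channel_labels=labels,
        fs=float(raw.info["sfreq"]),
        data=data_uv,
        subject_id=str(raw.info.get("subject_info") or ""),
    )
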