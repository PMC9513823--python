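"""In-memory EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np


@dataclass
class EEGRecording:
    """A multi-channel EEG recording in microvolts.

    Attributes
    ----------
    channel_labels : ordered channel names (ten-twenty labels).
    fs : sampling rate in Hz.
    data : ``(n_channels, n_samples)`` float array, physical units uV.
    subject_id : subject identifier.
    class_label : one of ``normal`` / ``TBI`` / ``stroke`` (or None).
    demographics : mapping with keys ``sex`` ("M"/"F"/"U"), ``age`` (years)
        and ``medication`` (unique-medication count).
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    subject_id: str = ""
    class_label: str | None = None
    demographics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but {self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        """Copy of this recording with new signal data (metadata preserved)."""
        return EEGRecording(
            channel_labels=list(self.channel_labels),
            fs=self.fs if fs is None else fs,
            data=np.asarray(data, dtype=float),
            subject_id=self.subject_id,
            class_label=self.class_label,
            demographics=dict(self.demographics),
        )

    def copy(self) -> "EEGRecording":
        return self.with_data(self.data.copy())
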