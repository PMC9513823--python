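"""Canonical 19-channel ten-twenty montage.

The canonical channel order fixes the ordering of every downstream feature
block (band powers, coherence pairs, entropy, PAC), so it must never change
between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical ten-twenty channel order. Index position defines feature order.
CHANNELS_1020: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "FZ", "CZ", "PZ",
)

N_CHANNELS = len(CHANNELS_1020)

#: Scalp-region channel groups used by the synthetic generator and the
#: heuristic IC labeler. "global" covers every channel.
CHANNEL_GROUPS: dict[str, tuple[str, ...]] = {
    "global": CHANNELS_1020,
    "frontal": ("FP1", "FP2", "F3", "F4", "F7", "F8", "FZ"),
    "central": ("C3", "C4", "CZ"),
    "parietal": ("P3", "P4", "P7", "P8", "PZ"),
    "temporal": ("T7", "T8"),
    "occipital": ("O1", "O2"),
}


def channel_index(label: str) -> int:
    return CHANNELS_1020.index(label.upper())


def channel_pairs(channels: tuple[str, ...] = CHANNELS_1020) -> list[tuple[str, str]]:
    """Upper-triangle channel pairs in canonical order (171 for 19 channels)."""
    n = len(channels)
    return [(channels[i], channels[j]) for i in range(n) for j in range(i + 1, n)]


N_PAIRS = len(channel_pairs())  # 171


@dataclass(frozen=True)
class MontageSpec:
    """Target montage: ordered ten-twenty channel list and sampling rate."""

    channels: tuple[str, ...] = CHANNELS_1020
    fs: float = 250.0

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("montage channels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


DEFAULT_MONTAGE = MontageSpec()
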