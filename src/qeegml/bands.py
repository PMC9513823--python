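"""Frequency-band scheme for qEEG feature generation.

Bands are half-open ``[lo, hi)`` intervals so adjacent bands never share a
spectral bin. The 20-25 Hz gap between beta and gamma is intentional and is
preserved as defined; the six bands therefore do not tile the 1-100 Hz
total-power interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BandScheme:
    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 1.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("mu", 12.0, 16.0),
        ("beta", 16.0, 20.0),
        ("gamma", 25.0, 40.0),
    )
    #: closed interval used for total power (relative-PSD denominator and
    #: the spectral-entropy domain)
    total: tuple[float, float] = (1.0, 100.0)
    #: broadband interval used for the group-contrast coherence maps
    broadband: tuple[float, float] = (1.0, 40.0)

    def __post_init__(self) -> None:
        intervals = sorted((lo, hi) for _, lo, hi in self.bands)
        for (lo, hi), (lo2, _) in zip(intervals, intervals[1:]):
            if hi > lo2:
                raise ValueError("bands must not overlap")
        for name, lo, hi in self.bands:
            if not (0 < lo < hi):
                raise ValueError(f"band {name}: need 0 < lo < hi")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    def interval(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return (lo, hi)
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.bands)


DEFAULT_BANDS = BandScheme()

#: PAC band pairings (phase band, amplitude band); the lower-frequency band
#: supplies the phase, the higher-frequency band the amplitude envelope.
PAC_PAIRINGS: tuple[tuple[str, str], ...] = (
    ("alpha", "gamma"),
    ("theta", "gamma"),
    ("theta", "alpha"),
)
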