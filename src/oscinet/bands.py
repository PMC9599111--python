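"""Frequency-band definitions.

The analysis is restricted to the alpha and beta bands, where
event-related power changes during motor imagery are band-specific
(ERD/ERS around ~10 and ~20 Hz); lower and higher bands tend to show
only unspecific synchronization and are not analysed.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got {self.lo}..{self.hi}")

    @property
    def center(self) -> float:
        """Band-center frequency in Hz, used as the phase-extraction carrier."""
        return 0.5 * (self.lo + self.hi)

    def check_nyquist(self, sampling_rate: float) -> None:
        if self.hi >= sampling_rate / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.hi} Hz is not below the "
                f"Nyquist frequency {sampling_rate / 2} Hz"
            )


ALPHA = BandSpec("alpha", 8.0, 13.0)
BETA = BandSpec("beta", 14.0, 29.0)

#: The two bands analysed by default.
DEFAULT_BANDS: tuple[BandSpec, ...] = (ALPHA, BETA)


def get_band(name: str) -> BandSpec:
    for band in DEFAULT_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in DEFAULT_BANDS]}")
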