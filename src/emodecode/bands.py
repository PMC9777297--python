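"""Frequency-band definitions shared by generation and feature extraction."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band {self.name}: ({self.f_lo}, {self.f_hi})")


# Canonical five-band split used for the time-frequency / FAA feature set.
# Delta is given a finite lower edge (1 Hz) and gamma a finite upper edge
# (45 Hz, below the muscle-artifact range) so the bands are computable.
TABLE_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 3.0),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 8.0, 15.0),
    BandSpec("beta", 16.0, 31.0),
    BandSpec("gamma", 32.0, 45.0),
)

# Seven-band split used for the envelope-correlation feature set: alpha is
# divided into low/high alpha and gamma into low/high gamma, the minimal
# refinement of the five-band table that yields seven bands including a
# distinct "high alpha".
CORRELATION_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 3.0),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("low_alpha", 8.0, 10.0),
    BandSpec("high_alpha", 11.0, 15.0),
    BandSpec("beta", 16.0, 31.0),
    BandSpec("low_gamma", 32.0, 45.0),
    BandSpec("high_gamma", 46.0, 60.0),
)

ALPHA = BandSpec("alpha", 8.0, 15.0)
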