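"""Closed-form sensor-characterization arithmetic.

Two small utilities used when characterising a dye–antibody conjugate:
the average dye-to-antibody ratio (DAR) from a MALDI mass shift, and the
Stokes shift from absorption/emission maxima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SpectraRecord", "dye_antibody_ratio", "stokes_shift"]


@dataclass
class SpectraRecord:
    """Absorption and emission maxima of a fluorophore, nm."""

    absorption_max: float
    emission_max: float

    def __post_init__(self):
        if self.absorption_max <= 0 or self.emission_max <= 0:
            raise ValueError("spectral maxima must be > 0")


def dye_antibody_ratio(mass_shift: float, dye_mass: float) -> float:
    """Average DAR = mass_shift / dye_mass, truncated to two decimals.

    Truncation (not rounding) matches the convention of reporting e.g.
    1015/749 = 1.3551... as 1.35.
    """
    if dye_mass <= 0:
        raise ValueError("dye_mass must be > 0")
    if mass_shift < 0:
        raise ValueError("mass_shift must be >= 0")
    return math.floor(100.0 * mass_shift / dye_mass) / 100.0


def stokes_shift(spectra: SpectraRecord) -> float:
    """Stokes shift = emission_max - absorption_max (nm); anti-Stokes
    (emission blue of absorption) is rejected as out of scope."""
    if spectra.emission_max < spectra.absorption_max:
        raise ValueError("emission_max < absorption_max (anti-Stokes not supported)")
    return spectra.emission_max - spectra.absorption_max
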