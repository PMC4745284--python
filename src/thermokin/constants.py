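"""Physical constants used by the denaturation thermodynamics.

Values are fixed to the precision conventionally quoted in enzyme
thermostability studies; they are deliberately not pulled from
``scipy.constants`` so that computed ΔG values are reproducible to the
last printed digit against published tables that used these roundings.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Universal gas constant, J K⁻¹ mol⁻¹.
R = 8.314

#: Planck constant, J s.
PLANCK_H = 6.626e-34

#: Boltzmann constant, J K⁻¹.
BOLTZMANN_KB = 1.3807e-23

#: Offset between Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the constants entering the Eyring expression."""

    r: float = R
    h: float = PLANCK_H
    kb: float = BOLTZMANN_KB


def celsius_to_kelvin(temperature_c: float) -> float:
    """Convert a temperature from °C to K."""
    return temperature_c + CELSIUS_OFFSET
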