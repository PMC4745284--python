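"""Arrhenius activation energy and Eyring denaturation thermodynamics.

The temperature dependence of the first-order denaturation constant is
summarized by the Arrhenius relation Kd ∝ exp(−Ea/RT): the activation
energy Ea of thermal inactivation is −R times the slope of an OLS fit of
ln Kd against 1/T (K), fitted once across all temperatures.

Per-temperature transition-state (Eyring) parameters then follow:

    ΔH = Ea − R·T                      (activation enthalpy)
    ΔG = −R·T · ln( Kd·h / (kb·T) )    (activation free energy)
    ΔS = (ΔH − ΔG) / T                 (activation entropy)

with h Planck's and kb Boltzmann's constant.  All energies are reported
in kJ/mol and ΔS in kJ/mol/K.

.. note:: **Kd unit convention inside ΔG.**  Dimensional rigor wants Kd
   in s⁻¹ inside the Eyring expression (kb·T/h is a frequency in s⁻¹).
   Published thermostability tables in this field, however, routinely
   insert Kd in min⁻¹, and the reference values this package reproduces
   follow that convention — so ``kd_units="per_min"`` (take the min⁻¹
   number as-is) is the default, and ``kd_units="per_sec"`` (divide by
   60 first) gives the SI-consistent variant, which shifts every ΔG up
   by R·T·ln 60 ≈ 12 kJ/mol at these temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .constants import BOLTZMANN_KB, PLANCK_H, R, celsius_to_kelvin
from .errors import ValidationError
from .kinetics import InactivationFit, half_life

__all__ = [
    "ArrheniusFit",
    "ThermoProfile",
    "arrhenius_fit",
    "enthalpy",
    "gibbs",
    "entropy",
    "thermo_profile",
]

KD_UNIT_CHOICES = ("per_min", "per_sec")


@dataclass(frozen=True)
class ArrheniusFit:
    """OLS fit of ln Kd on 1/T (K).

    ``slope`` is in K (= −Ea/R); ``ea`` is the activation energy of
    thermal inactivation in kJ/mol; ``points`` are the (T in K, Kd in
    min⁻¹) pairs used.
    """

    ea: float
    slope: float
    intercept: float
    r_squared: float
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not math.isclose(self.ea, -self.slope * R / 1000.0, rel_tol=1e-9):
            raise ValidationError("ea must equal −slope × R (kJ/mol)")


@dataclass(frozen=True)
class ThermoProfile:
    """Kinetic and thermodynamic denaturation parameters at one temperature.

    Energies in kJ/mol, ΔS in kJ/mol/K, Kd in min⁻¹, t½ in min.
    ΔS satisfies ΔS·T = ΔH − ΔG exactly by construction.
    """

    temperature_c: float
    temperature_k: float
    kd: float
    t_half: float
    dH: float
    dG: float
    dS: float

    def __post_init__(self) -> None:
        if not math.isclose(
            self.temperature_k, celsius_to_kelvin(self.temperature_c), abs_tol=1e-9
        ):
            raise ValidationError("temperature_k must be temperature_c + 273.15")


def _as_per_min(kd: float, kd_units: str) -> float:
    """Return the numeric value to insert in the Eyring log argument."""
    if kd_units not in KD_UNIT_CHOICES:
        raise ValidationError(f"kd_units must be one of {KD_UNIT_CHOICES}, got {kd_units!r}")
    return kd / 60.0 if kd_units == "per_sec" else kd


def arrhenius_fit(points: Iterable[tuple[float, float]]) -> ArrheniusFit:
    """Fit ln Kd against 1/T(K) by OLS over (temperature_c, kd) pairs.

    Requires at least two distinct temperatures and all kd > 0.
    """
    pts = [(float(t), float(k)) for t, k in points]
    if any(k <= 0 for _, k in pts):
        raise ValidationError("all kd must be > 0 for an Arrhenius fit")
    temps_k = np.array([celsius_to_kelvin(t) for t, _ in pts])
    if len(np.unique(temps_k)) < 2:
        raise ValidationError("Arrhenius fit needs ≥2 distinct temperatures")
    kd = np.array([k for _, k in pts])
    ols = stats.linregress(1.0 / temps_k, np.log(kd))
    slope = float(ols.slope)
    return ArrheniusFit(
        ea=-slope * R / 1000.0,
        slope=slope,
        intercept=float(ols.intercept),
        r_squared=float(ols.rvalue) ** 2,
        points=tuple(zip(temps_k.tolist(), kd.tolist())),
    )


def enthalpy(ea: float, temperature_c: float) -> float:
    """Activation enthalpy ΔH = Ea − R·T, in kJ/mol (``ea`` in kJ/mol)."""
    return ea - R * celsius_to_kelvin(temperature_c) / 1000.0


def gibbs(kd: float, temperature_c: float, kd_units: str = "per_min") -> float:
    """Activation free energy ΔG = −R·T·ln(Kd·h/(kb·T)), in kJ/mol.

    ``kd`` is the denaturation constant in min⁻¹.  See the module note
    on the ``kd_units`` convention; the default inserts the min⁻¹ value
    directly, matching published tables.
    """
    if kd <= 0:
        raise ValidationError(f"gibbs requires kd > 0, got {kd}")
    t_k = celsius_to_kelvin(temperature_c)
    kd_num = _as_per_min(kd, kd_units)
    return -R * t_k * math.log(kd_num * PLANCK_H / (BOLTZMANN_KB * t_k)) / 1000.0


def entropy(dH: float, dG: float, temperature_c: float) -> float:
    """Activation entropy ΔS = (ΔH − ΔG)/T, in kJ/mol/K."""
    return (dH - dG) / celsius_to_kelvin(temperature_c)


def thermo_profile(
    fits: Sequence[InactivationFit] | Sequence[tuple[float, float]],
    kd_units: str = "per_min",
) -> tuple[ArrheniusFit, list[ThermoProfile]]:
    """Build the full thermodynamic table from per-temperature rate constants.

    Accepts either :class:`InactivationFit` objects or bare
    ``(temperature_c, kd)`` pairs.  Fits one global Arrhenius line, then
    computes ΔH from the shared Ea and ΔG from each temperature's own
    Kd; ΔS is derived so the ΔS·T = ΔH − ΔG identity holds row-wise.
    """
    pairs: list[tuple[float, float]] = []
    for f in fits:
        if isinstance(f, InactivationFit):
            if f.non_decaying:
                raise ValidationError(
                    f"non-decaying course at {f.temperature_c} °C has no usable kd"
                )
            pairs.append((f.temperature_c, f.kd))
        else:
            t, k = f
            pairs.append((float(t), float(k)))

    arr = arrhenius_fit(pairs)
    profiles = []
    for t_c, kd in pairs:
        dH = enthalpy(arr.ea, t_c)
        dG = gibbs(kd, t_c, kd_units=kd_units)
        profiles.append(
            ThermoProfile(
                temperature_c=t_c,
                temperature_k=celsius_to_kelvin(t_c),
                kd=kd,
                t_half=half_life(kd),
                dH=dH,
                dG=dG,
                dS=entropy(dH, dG, t_c),
            )
        )
    return arr, profiles
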