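"""Synthetic thermostability data with Arrhenius-consistent kinetics.

The generator stands in for wet-lab measurements: it produces
residual-activity time courses whose true rate constants follow an
Arrhenius law across a temperature sweep, with multiplicative lognormal
measurement noise and optional stabilizer protection factors, plus
designed purification ledgers.  Every pipeline stage is therefore
testable end-to-end with known ground truth.

Forward model
-------------
Rate constants are parameterized by a reference point rather than a
pre-exponential factor:

    kd(T) = kd_ref · exp[ −Ea/R · (1/T − 1/T_ref) ]     (T in K)

so kd(T_ref) = kd_ref exactly.  A condition's effective constant is
kd_eff = kd(T) · protection_factor; factors < 1 model thermoprotectants
(divalent cations, polyols) that slow inactivation.  Residual activity
is 100·exp(−kd_eff·t)·ε_t with ε_t lognormal, mean 1, coefficient of
variation ``noise_cv`` (multiplicative noise: activities are positive
and titration error scales with signal; additive Gaussian is available
as an option).

The default scenario mirrors a hyperthermostable lipase characterized
over 80–120 °C: kd_ref = 4.6×10⁻³ min⁻¹ at 80 °C (t½ ≈ 150 min),
Ea = 31.102 kJ/mol, residual activity sampled every 30 min over 3 h.

Randomness is driven by one global seed through a splittable stream per
(temperature, condition), so adding a condition never perturbs the
draws of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import R, celsius_to_kelvin
from .errors import ValidationError
from .kinetics import TimeCourse

__all__ = ["SimulationScenario", "simulate_kd", "simulate_timecourse", "simulate_ledger"]

DEFAULT_TEMPERATURES = (80.0, 90.0, 100.0, 110.0, 120.0)
DEFAULT_TIME_GRID = tuple(float(t) for t in range(0, 181, 30))


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth parameters for a simulated thermostability study.

    ``protection_factors`` maps condition labels to multipliers on kd;
    the implicit ``"control"`` condition has factor 1 unless overridden.
    ``noise_cv`` is the coefficient of variation of the multiplicative
    lognormal measurement noise (0 disables noise).
    """

    ea_true: float = 31.102  # kJ/mol
    kd_ref: float = 46e-4  # min⁻¹ at t_ref
    t_ref: float = 80.0  # °C
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    noise_cv: float = 0.02
    protection_factors: Mapping[str, float] = field(default_factory=dict)
    noise_model: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ea_true < 0:
            raise ValidationError("ea_true must be ≥ 0 kJ/mol")
        if self.kd_ref <= 0:
            raise ValidationError("kd_ref must be > 0 min⁻¹")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be ≥ 0")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if any(f <= 0 for f in self.protection_factors.values()):
            raise ValidationError("protection factors must be > 0")
        object.__setattr__(self, "temperatures", tuple(float(t) for t in self.temperatures))
        object.__setattr__(self, "time_grid", tuple(float(t) for t in self.time_grid))
        object.__setattr__(self, "protection_factors", dict(self.protection_factors))

    def protection_factor(self, condition: str) -> float:
        if condition in self.protection_factors:
            return self.protection_factors[condition]
        if condition == "control":
            return 1.0
        raise ValidationError(
            f"unknown condition {condition!r}; known: "
            f"{['control', *self.protection_factors]}"
        )


def simulate_kd(scenario: SimulationScenario, temperature_c: float) -> float:
    """True (noise-free) denaturation constant at ``temperature_c``, min⁻¹."""
    t_k = celsius_to_kelvin(temperature_c)
    t_ref_k = celsius_to_kelvin(scenario.t_ref)
    ea_j = scenario.ea_true * 1000.0
    return scenario.kd_ref * math.exp(-(ea_j / R) * (1.0 / t_k - 1.0 / t_ref_k))


def _stream(scenario: SimulationScenario, temperature_c: float, condition: str):
    """Independent, reproducible RNG per (temperature, condition)."""
    key = (
        scenario.seed,
        int(round(temperature_c * 100)) & 0x7FFFFFFF,
        zlib.crc32(condition.encode("utf-8")),
    )
    return np.random.default_rng(key)


def simulate_timecourse(
    scenario: SimulationScenario,
    temperature_c: float,
    condition: str = "control",
) -> TimeCourse:
    """Draw one residual-activity time course under the scenario.

    Deterministic given (scenario, temperature, condition): the same
    seed always yields the identical course.
    """
    factor = scenario.protection_factor(condition)
    kd_eff = simulate_kd(scenario, temperature_c) * factor
    t = np.asarray(scenario.time_grid, dtype=float)
    clean = 100.0 * np.exp(-kd_eff * t)

    if scenario.noise_cv > 0:
        rng = _stream(scenario, temperature_c, condition)
        if scenario.noise_model == "lognormal":
            # mean-1 lognormal with the requested CV
            sigma = math.sqrt(math.log(1.0 + scenario.noise_cv**2))
            eps = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.size)
            noisy = clean * eps
        else:
            noisy = np.clip(clean + rng.normal(0.0, scenario.noise_cv * clean), 0.0, None)
    else:
        noisy = clean

    return TimeCourse(
        temperature_c=float(temperature_c),
        times=tuple(t.tolist()),
        residuals=tuple(noisy.tolist()),
        condition=condition,
    )


def simulate_study(
    scenario: SimulationScenario, conditions: Sequence[str] = ("control",)
) -> list[TimeCourse]:
    """All (temperature × condition) courses of a scenario."""
    return [
        simulate_timecourse(scenario, t, c)
        for c in conditions
        for t in scenario.temperatures
    ]


def simulate_ledger(
    seed: int = 0,
    n_steps: int = 4,
    step_recoveries: Sequence[float] | None = None,
    step_purities: Sequence[float] | None = None,
    crude_activity_u: float = 150000.0,
    crude_specific_u_mg: float = 175.0,
) -> list[tuple[str, float, float]]:
    """Construct a purification ledger with a designed fold/yield trajectory.

    ``step_recoveries[i]`` is the fraction of total activity surviving
    step i+1 relative to step i (in (0, 1]); ``step_purities[i]`` is the
    factor by which specific activity improves (≥ 1).  By construction,
    deriving fold/yield from the returned ledger reproduces the
    cumulative products of these factors exactly.  When either sequence
    is omitted, plausible values are drawn from ``seed``.
    """
    if n_steps < 1:
        raise ValidationError("n_steps must be ≥ 1")
    rng = np.random.default_rng(seed)
    if step_recoveries is None:
        step_recoveries = rng.uniform(0.1, 0.8, size=n_steps - 1).tolist()
    if step_purities is None:
        step_purities = rng.uniform(1.5, 4.0, size=n_steps - 1).tolist()
    step_recoveries = [float(x) for x in step_recoveries]
    step_purities = [float(x) for x in step_purities]
    if len(step_recoveries) != n_steps - 1 or len(step_purities) != n_steps - 1:
        raise ValidationError("need exactly n_steps − 1 recoveries and purities")
    if any(not (0.0 < r <= 1.0) for r in step_recoveries):
        raise ValidationError("recoveries must lie in (0, 1]")
    if any(p < 1.0 for p in step_purities):
        raise ValidationError("purity gains must be ≥ 1")

    names = ["crude"] + [f"step_{i}" for i in range(1, n_steps)]
    ledger = []
    activity = crude_activity_u
    spec = crude_specific_u_mg
    ledger.append((names[0], activity / spec, activity))
    for name, rec, pur in zip(names[1:], step_recoveries, step_purities):
        activity = activity * rec
        spec = spec * pur
        ledger.append((name, activity / spec, activity))
    return ledger
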