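"""First-order thermal inactivation kinetics.

Irreversible thermal denaturation of an enzyme at constant temperature is
modeled as a single-exponential decay of residual activity,

    A(t) = A(0) · exp(−Kd · t),

where Kd (min⁻¹) is the first-order denaturation rate constant.  Kd is
estimated classically, as the negative slope of an ordinary least-squares
fit of ln(residual activity) against time — the "plot of residual
activity versus time" treatment — and the half-life is t½ = ln 2 / Kd.

A direct nonlinear least-squares fit of the exponential is available
behind ``method="nonlinear"`` but is not the default: the log-linear
treatment is what published half-life and Arrhenius numbers in this
field are built on, and the two agree exactly on noise-free data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import InsufficientDataError, ValidationError

__all__ = ["TimeCourse", "InactivationFit", "fit_first_order", "half_life"]


@dataclass(frozen=True)
class TimeCourse:
    """Residual activity (%) sampled over time at one temperature/condition.

    ``times`` are minutes, non-negative and strictly increasing with the
    first point at t = 0; ``residuals`` are percent residual activity
    aligned to ``times`` (non-negative; zeros are legal and are excluded
    from log-linear fitting rather than imputed).
    """

    temperature_c: float
    times: tuple[float, ...]
    residuals: tuple[float, ...]
    condition: str = "control"

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        residuals = tuple(float(r) for r in self.residuals)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "residuals", residuals)
        if len(times) != len(residuals):
            raise ValidationError(
                f"times ({len(times)}) and residuals ({len(residuals)}) differ in length"
            )
        if len(times) == 0:
            raise ValidationError("empty time course")
        if times[0] < 0:
            raise ValidationError("times must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("times must be strictly increasing")
        if any(r < 0 for r in residuals):
            raise ValidationError("residual activities must be ≥ 0")


@dataclass(frozen=True)
class InactivationFit:
    """Fitted first-order denaturation constant for one time course.

    ``kd`` is in min⁻¹; ``t_half = ln2/kd`` (infinite for non-decaying
    courses, where kd ≤ 0 and ``non_decaying`` is set).  ``intercept`` is
    the fitted ln(residual) at t = 0, retained as a diagnostic — the fit
    is not forced through ln(100).  ``excluded_points`` are the indices of
    points with residual ≤ 0, excluded from the log fit.
    """

    temperature_c: float
    kd: float
    t_half: float
    r_squared: float
    intercept: float
    n_points_used: int
    excluded_points: tuple[int, ...] = ()
    non_decaying: bool = False
    condition: str = "control"
    method: str = "log-linear"

    def __post_init__(self) -> None:
        if not self.non_decaying:
            if self.kd <= 0:
                raise ValidationError("decaying fit requires kd > 0")
            if not math.isclose(self.t_half * self.kd, math.log(2.0), rel_tol=1e-12):
                raise ValidationError("t_half × kd must equal ln 2")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError(f"r² out of range: {self.r_squared}")


def half_life(kd: float) -> float:
    """Half-life (min) of a first-order decay with rate constant ``kd`` (min⁻¹)."""
    if kd <= 0:
        raise ValidationError(f"half-life requires kd > 0, got {kd}")
    return math.log(2.0) / kd


def _fit_nonlinear(t: np.ndarray, r: np.ndarray, kd0: float, a0: float):
    """Exponential fit r = a·exp(−kd·t); returns (kd, ln a, r² on log scale)."""

    def model(t, a, kd):
        return a * np.exp(-kd * t)

    (a, kd), _ = optimize.curve_fit(model, t, r, p0=(a0, kd0), maxfev=10000)
    pred = np.log(model(t, a, kd))
    obs = np.log(r)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return kd, math.log(a), min(r2, 1.0)


def fit_first_order(tc: TimeCourse, method: str = "log-linear") -> InactivationFit:
    """Fit the first-order denaturation constant of one time course.

    Points with residual ≤ 0 are excluded (logged in
    ``excluded_points``); at least 3 positive-residual points are
    required.  A non-positive decay slope does not raise — the fit is
    returned with ``kd ≤ 0``, an infinite half-life and the
    ``non_decaying`` flag set, so screening over many conditions does
    not abort on a stable one.

    Parameters
    ----------
    tc : TimeCourse
    method : {"log-linear", "nonlinear"}
        ``"log-linear"`` (default): OLS of ln(residual) on time.
        ``"nonlinear"``: least-squares fit of the exponential itself.
    """
    if method not in ("log-linear", "nonlinear"):
        raise ValidationError(f"unknown fit method {method!r}")

    t_all = np.asarray(tc.times, dtype=float)
    r_all = np.asarray(tc.residuals, dtype=float)
    usable = r_all > 0
    excluded = tuple(int(i) for i in np.nonzero(~usable)[0])
    t, r = t_all[usable], r_all[usable]

    if len(t) < 3:
        raise InsufficientDataError(
            f"need ≥3 points with residual > 0 to fit "
            f"({tc.temperature_c} °C, {tc.condition!r}): have {len(t)}"
        )

    ols = stats.linregress(t, np.log(r))
    slope, intercept = float(ols.slope), float(ols.intercept)
    r2 = float(ols.rvalue) ** 2

    if method == "nonlinear":
        kd0 = max(-slope, 1e-6)
        kd, intercept, r2 = _fit_nonlinear(t, r, kd0, math.exp(intercept))
    else:
        kd = -slope

    non_decaying = kd <= 0
    return InactivationFit(
        temperature_c=tc.temperature_c,
        kd=kd,
        t_half=math.inf if non_decaying else math.log(2.0) / kd,
        r_squared=min(r2, 1.0),
        intercept=intercept,
        n_points_used=len(t),
        excluded_points=excluded,
        non_decaying=non_decaying,
        condition=tc.condition,
        method=method,
    )
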