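"""SDS-PAGE molecular-weight calibration from relative migration (Rf).

On a denaturing gel, log10 of molecular weight is approximately linear
in the relative migration Rf (band distance / dye-front distance).  A
standard curve is fitted by OLS of log10(MW) on Rf over marker proteins
of known mass; an unknown band's mass is then 10^(slope·Rf + intercept).
Base-10 logarithms are the plotting convention; the choice of base does
not affect predicted masses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnfittedModelError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["Marker", "MarkerSet", "GelCalibration", "calibrate", "estimate_mw",
           "STANDARD_MARKER_MW_KDA"]

#: Broad-range unstained protein standards (kDa) of the HiPer SDS-PAGE kit.
STANDARD_MARKER_MW_KDA = {
    "insulin": 3.5,
    "aprotinin": 6.5,
    "lysozyme": 14.3,
    "soybean trypsin inhibitor": 20.1,
    "carbonic anhydrase": 29.0,
    "ovalbumin": 43.0,
    "BSA": 66.0,
    "phosphorylase": 97.4,
    "myosin": 205.0,
}


@dataclass(frozen=True)
class Marker:
    """One marker lane entry: protein name, mass (kDa), relative migration."""

    name: str
    mw_kda: float
    rf: float

    def __post_init__(self) -> None:
        if self.mw_kda <= 0:
            raise ValidationError(f"marker {self.name!r}: mw must be > 0 kDa")
        if not (0.0 < self.rf < 1.0):
            raise ValidationError(f"marker {self.name!r}: rf must lie in (0, 1)")


@dataclass(frozen=True)
class MarkerSet:
    """Marker standards for one gel; Rf must decrease as MW increases."""

    markers: tuple[Marker, ...]

    def __init__(self, markers: Iterable[Marker], strict: bool = True) -> None:
        mk = tuple(markers)
        if len(mk) < 3:
            raise ValidationError(f"need ≥3 markers to calibrate a gel, got {len(mk)}")
        by_mw = sorted(mk, key=lambda m: m.mw_kda)
        rfs = [m.rf for m in by_mw]
        if any(b >= a for a, b in zip(rfs, rfs[1:])):
            msg = "Rf is not strictly decreasing with increasing MW (non-monotonic gel)"
            if strict:
                raise ValidationError(msg)
            logger.warning(msg)
        object.__setattr__(self, "markers", mk)

    @property
    def rf_range(self) -> tuple[float, float]:
        rfs = [m.rf for m in self.markers]
        return min(rfs), max(rfs)


@dataclass(frozen=True)
class GelCalibration:
    """Fitted standard curve: log10(MW/kDa) = slope·Rf + intercept."""

    slope: float
    intercept: float
    r_squared: float
    rf_range: tuple[float, float]


def calibrate(markers: MarkerSet) -> GelCalibration:
    """Fit log10(MW) on Rf by OLS.  Slope is negative for a valid gel."""
    rf = np.array([m.rf for m in markers.markers])
    log_mw = np.log10([m.mw_kda for m in markers.markers])
    ols = stats.linregress(rf, log_mw)
    if ols.slope >= 0:
        raise ValidationError(
            "calibration slope is non-negative; check Rf orientation (larger "
            "proteins should migrate less)"
        )
    return GelCalibration(
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        r_squared=float(ols.rvalue) ** 2,
        rf_range=markers.rf_range,
    )


def estimate_mw(model: GelCalibration, rf: float) -> float:
    """Estimate a band's molecular weight (kDa) from its Rf.

    Warns when ``rf`` lies outside the marker range (extrapolation);
    interpolated estimates are the reliable ones.
    """
    if model is None:
        raise UnfittedModelError("gel calibration model is not fitted")
    if not (0.0 <= rf <= 1.0):
        raise ValidationError(f"rf must lie in [0, 1], got {rf}")
    lo, hi = model.rf_range
    if not (lo <= rf <= hi):
        logger.warning(
            "rf %.3f outside marker range [%.3f, %.3f]: extrapolating", rf, lo, hi
        )
    return float(10.0 ** (model.slope * rf + model.intercept))


def read_markers_csv(path, strict: bool = True) -> MarkerSet:
    """Read a marker table CSV with columns ``name, mw_kda, rf``."""
    df = pd.read_csv(path)
    missing = [c for c in ("name", "mw_kda", "rf") if c not in df.columns]
    if missing:
        raise ValidationError(f"marker table {path} is missing columns {missing}")
    return MarkerSet(
        (Marker(str(r.name), float(r.mw_kda), float(r.rf)) for r in df.itertuples()),
        strict=strict,
    )
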