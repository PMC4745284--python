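"""Titrimetric lipase activity units and residual-activity normalization.

The titrimetric assay quantifies lipase activity by the free fatty acid
released from an olive-oil emulsion: the acid is back-titrated with NaOH,
and one unit (U) is the amount of enzyme releasing 1 μmol of fatty acid
under the fixed assay conditions.  The unit is defined *per assay* (one
fixed incubation), not per minute; the incubation time is carried on the
reading for provenance but never used to rescale the unit.

Residual activity expresses an activity as a percentage of a reference
(typically the unstressed, t = 0 measurement).  Values above 100% are
legal — additives such as Mg²⁺ can activate the enzyme severalfold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Default titrant molarity (mol/L) of the standard assay.
DEFAULT_NAOH_MOLARITY = 0.05

#: Default incubation time (min) of the standard assay.
DEFAULT_INCUBATION_MIN = 30.0


@dataclass(frozen=True)
class TitrationReading:
    """One titrimetric assay measurement.

    Parameters
    ----------
    v_test_ml : float
        NaOH volume (mL) consumed titrating the enzyme-containing assay.
    v_blank_ml : float
        NaOH volume (mL) consumed titrating the enzyme-free blank.
    naoh_molarity : float
        Titrant concentration, mol/L.
    enzyme_volume_ml : float
        Volume of enzyme preparation added to the assay, mL.
    incubation_time_min : float
        Assay incubation time in minutes.  Provenance only; units are
        defined per assay, not per minute.
    """

    v_test_ml: float
    v_blank_ml: float
    naoh_molarity: float = DEFAULT_NAOH_MOLARITY
    enzyme_volume_ml: float = 1.0
    incubation_time_min: float = DEFAULT_INCUBATION_MIN

    def __post_init__(self) -> None:
        if self.v_test_ml < 0 or self.v_blank_ml < 0:
            raise ValidationError(
                f"titrant volumes must be non-negative, got "
                f"v_test={self.v_test_ml}, v_blank={self.v_blank_ml}"
            )
        if self.naoh_molarity <= 0:
            raise ValidationError(f"NaOH molarity must be > 0, got {self.naoh_molarity}")
        if self.enzyme_volume_ml <= 0:
            raise ValidationError(f"enzyme volume must be > 0, got {self.enzyme_volume_ml}")
        if self.incubation_time_min <= 0:
            raise ValidationError(
                f"incubation time must be > 0, got {self.incubation_time_min}"
            )


@dataclass(frozen=True)
class Activity:
    """Lipase activity in U/mL (1 U = 1 μmol fatty acid per assay)."""

    units_per_ml: float

    def __post_init__(self) -> None:
        if self.units_per_ml < 0:
            raise ValidationError(f"activity must be ≥ 0, got {self.units_per_ml}")


def titration_to_units(reading: TitrationReading) -> Activity:
    """Convert a titration reading to lipase activity.

    The net titrant volume (test − blank, mL) times molarity (mmol/mL)
    gives mmol of fatty acid neutralized; ×1000 converts to μmol, i.e.
    units, and dividing by the enzyme volume yields U/mL.

    A test volume below the blank (no detectable activity plus titration
    noise) is clamped to zero activity with a warning rather than
    reported negative.
    """
    net_ml = reading.v_test_ml - reading.v_blank_ml
    if net_ml < 0:
        logger.warning(
            "test titre %.4g mL below blank %.4g mL; clamping activity to 0 U/mL",
            reading.v_test_ml,
            reading.v_blank_ml,
        )
        net_ml = 0.0
    umol = net_ml * reading.naoh_molarity * 1000.0
    return Activity(units_per_ml=umol / reading.enzyme_volume_ml)


def residual_activity(activity_t: Activity, activity_ref: Activity) -> float:
    """Percent residual activity of ``activity_t`` relative to ``activity_ref``.

    May exceed 100% (activation).  Raises :class:`ValidationError` when the
    reference activity is zero, since the ratio is undefined.
    """
    if activity_ref.units_per_ml <= 0:
        raise ValidationError(
            "reference activity is zero; residual activity is undefined "
            "(choose a reference measurement with nonzero activity)"
        )
    return 100.0 * activity_t.units_per_ml / activity_ref.units_per_ml


#: Required columns of a titration CSV table.
TITRATION_COLUMNS = [
    "sample_id",
    "v_test_ml",
    "v_blank_ml",
    "naoh_molarity",
    "enzyme_volume_ml",
    "time_min",
]


def read_titration_csv(path) -> pd.DataFrame:
    """Read a titration table and append a computed ``units_per_ml`` column.

    Expected columns: ``sample_id, v_test_ml, v_blank_ml, naoh_molarity,
    enzyme_volume_ml, time_min``.
    """
    df = pd.read_csv(path)
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"titration table {path} is missing columns {missing}")
    units = []
    for row in df.itertuples(index=False):
        reading = TitrationReading(
            v_test_ml=row.v_test_ml,
            v_blank_ml=row.v_blank_ml,
            naoh_molarity=row.naoh_molarity,
            enzyme_volume_ml=row.enzyme_volume_ml,
            incubation_time_min=row.time_min,
        )
        units.append(titration_to_units(reading).units_per_ml)
    out = df.copy()
    out["units_per_ml"] = units
    return out
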