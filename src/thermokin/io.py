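"""CSV readers/writers shared by the library, CLI and pipeline.

Dialect: UTF-8, comma-separated, mandatory header row, '.' decimal.
Temperatures are °C in every user-facing file; Kelvin exists only
inside computations.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .kinetics import InactivationFit, TimeCourse
from .thermo import ArrheniusFit, ThermoProfile

TIMECOURSE_COLUMNS = ["temperature_c", "condition", "time_min", "residual_pct"]
FIT_COLUMNS = [
    "temperature_c",
    "condition",
    "kd_per_min",
    "t_half_min",
    "r_squared",
    "intercept",
    "n_points_used",
    "non_decaying",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def read_timecourses_csv(path) -> list[TimeCourse]:
    """Read residual-activity courses; one file may hold many
    (temperature, condition) groups, each sorted by time."""
    df = pd.read_csv(path)
    _require_columns(df, TIMECOURSE_COLUMNS, path)
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    courses = []
    for (temp, cond), grp in df.groupby(["temperature_c", "condition"], sort=True):
        grp = grp.sort_values("time_min")
        courses.append(
            TimeCourse(
                temperature_c=float(temp),
                times=tuple(grp["time_min"].astype(float)),
                residuals=tuple(grp["residual_pct"].astype(float)),
                condition=str(cond),
            )
        )
    return courses


def write_timecourses_csv(courses: Sequence[TimeCourse], path) -> None:
    rows = [
        (c.temperature_c, c.condition, t, r)
        for c in courses
        for t, r in zip(c.times, c.residuals)
    ]
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(path, index=False)


def fits_frame(fits: Sequence[InactivationFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "temperature_c": [f.temperature_c for f in fits],
            "condition": [f.condition for f in fits],
            "kd_per_min": [f.kd for f in fits],
            "t_half_min": [f.t_half for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "intercept": [f.intercept for f in fits],
            "n_points_used": [f.n_points_used for f in fits],
            "non_decaying": [f.non_decaying for f in fits],
        }
    )


def write_fits_csv(fits: Sequence[InactivationFit], path) -> None:
    fits_frame(fits).to_csv(path, index=False)


def read_fits_csv(path) -> list[tuple[float, float]]:
    """Read (temperature_c, kd) pairs from a fits CSV (control rows only
    if a condition column is present with several conditions)."""
    df = pd.read_csv(path)
    _require_columns(df, ["temperature_c", "kd_per_min"], path)
    if "non_decaying" in df.columns:
        df = df[~df["non_decaying"].astype(bool)]
    if df.empty:
        raise ValidationError(f"{path}: no decaying fits to use")
    return [
        (float(r.temperature_c), float(r.kd_per_min)) for r in df.itertuples()
    ]


def thermo_frame(profiles: Sequence[ThermoProfile]) -> pd.DataFrame:
    """Denaturation table in the conventional layout (energies kJ/mol)."""
    return pd.DataFrame(
        {
            "temperature_c": [p.temperature_c for p in profiles],
            "t_half_min": [p.t_half for p in profiles],
            "kd_per_min": [p.kd for p in profiles],
            "dH_kJ_mol": [p.dH for p in profiles],
            "dG_kJ_mol": [p.dG for p in profiles],
            "dS_kJ_mol_K": [p.dS for p in profiles],
        }
    )


def arrhenius_summary(fit: ArrheniusFit) -> dict:
    return {
        "ea_kJ_mol": fit.ea,
        "slope_K": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "n_temperatures": len(fit.points),
    }


def file_sha256(path) -> str:
    """Provenance hash of an input file."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
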