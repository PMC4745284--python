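"""Purification-table accounting: specific activity, fold, and yield.

A purification ledger is an ordered list of steps, the first being the
crude extract.  For each step, specific activity = total activity /
total protein (U/mg); purification fold = specific activity relative to
the crude step; yield = percent of crude total activity retained.  Fold
and yield are dimensionless ratios, invariant under any common rescaling
of the protein or activity columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

__all__ = ["PurificationStep", "specific_activity", "build_ledger", "ledger_frame"]


@dataclass(frozen=True)
class PurificationStep:
    """One row of a purification ledger, with derived columns filled in."""

    name: str
    protein_mg: float
    total_activity_u: float
    specific_activity_u_mg: float
    fold: float
    yield_pct: float


def specific_activity(total_activity: float, protein: float) -> float:
    """Specific activity (U/mg) = total activity (U) / total protein (mg)."""
    if protein <= 0:
        raise ValidationError(f"protein must be > 0 mg, got {protein}")
    if total_activity < 0:
        raise ValidationError(f"total activity must be ≥ 0 U, got {total_activity}")
    return total_activity / protein


def build_ledger(
    steps: Sequence[tuple[str, float, float]] | Iterable[tuple[str, float, float]],
) -> list[PurificationStep]:
    """Derive specific activity, fold and yield for an ordered ledger.

    ``steps`` are (name, protein_mg, total_activity_u) tuples; the first
    step is the crude reference (fold 1, yield 100 by definition).  All
    values are computed at full precision; rounding is a concern of
    report serialization only.
    """
    rows = list(steps)
    if not rows:
        raise ValidationError("empty purification ledger")
    crude_name, crude_protein, crude_activity = rows[0]
    if crude_activity <= 0:
        raise ValidationError(
            f"crude step {crude_name!r} has zero total activity; fold/yield undefined"
        )
    crude_specific = specific_activity(crude_activity, crude_protein)

    out = []
    for name, protein, activity in rows:
        spec = specific_activity(activity, protein)
        out.append(
            PurificationStep(
                name=name,
                protein_mg=float(protein),
                total_activity_u=float(activity),
                specific_activity_u_mg=spec,
                fold=spec / crude_specific,
                yield_pct=100.0 * activity / crude_activity,
            )
        )
    return out


def ledger_frame(steps: Sequence[PurificationStep]) -> pd.DataFrame:
    """Tabulate a derived ledger as a DataFrame (full precision)."""
    return pd.DataFrame(
        {
            "step": [s.name for s in steps],
            "protein_mg": [s.protein_mg for s in steps],
            "total_activity_u": [s.total_activity_u for s in steps],
            "specific_activity_u_mg": [s.specific_activity_u_mg for s in steps],
            "fold": [s.fold for s in steps],
            "yield_pct": [s.yield_pct for s in steps],
        }
    )


def read_ledger_csv(path) -> list[PurificationStep]:
    """Read a ledger CSV with columns ``step, protein_mg, total_activity_u``."""
    df = pd.read_csv(path)
    missing = [c for c in ("step", "protein_mg", "total_activity_u") if c not in df.columns]
    if missing:
        raise ValidationError(f"ledger {path} is missing columns {missing}")
    return build_ledger(
        [(str(r.step), float(r.protein_mg), float(r.total_activity_u)) for r in df.itertuples()]
    )
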