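"""Bundled reference data: published characterization of a
hyperthermostable alkaline *Bacillus sonorensis* lipase.

These are the printed kinetic/thermodynamic and purification tables of
a desert-isolate lipase stable at 80–120 °C, used throughout the tests
and examples as a real-world consistency check.  Rate constants are in
min⁻¹; the t½, ΔH, ΔG, ΔS columns are the published values (derived
quantities recomputed by this package agree with them except where
noted in docs/methods.md).
"""

from __future__ import annotations

#: (temperature °C, Kd min⁻¹) pairs of the published denaturation table.
LIPASE_KD_TABLE: tuple[tuple[float, float], ...] = (
    (80.0, 46e-4),
    (90.0, 57e-4),
    (100.0, 77e-4),
    (110.0, 99e-4),
    (120.0, 138e-4),
)

#: Published half-lives (min) aligned with LIPASE_KD_TABLE.
LIPASE_T_HALF_MIN = (150.0, 121.59, 90.01, 70.01, 50.0)

#: Published activation energy of thermal inactivation, kJ/mol.
LIPASE_EA_KJ_MOL = 31.102

#: Published per-temperature ΔH (kJ/mol), aligned with LIPASE_KD_TABLE.
LIPASE_DH_KJ_MOL = (28.16, 28.08, 28.00, 27.91, 27.83)

#: Published per-temperature ΔG (kJ/mol).  The 100 °C and 120 °C entries
#: are not consistent with the Eyring expression evaluated on their own
#: Kd (see docs/methods.md) and are excluded from strict checks.
LIPASE_DG_KJ_MOL = (102.79, 105.12, 110.28, 109.32, 111.66)

#: Indices into the table whose printed ΔG matches direct evaluation.
LIPASE_DG_CONSISTENT_ROWS = (0, 1, 3)

#: Published per-temperature ΔS (kJ/mol/K; the source table's header
#: says J/mol/K but the magnitudes are kJ-scale).
LIPASE_DS_KJ_MOL_K = (-0.211, -0.212, -0.220, -0.212, -0.211)

#: Published purification ledger: (step, total activity U,
#: specific activity U/mg, fold, yield %).  Protein is listed per mL in
#: the source without volumes, so only the printed specific/total
#: activity columns are reusable.
LIPASE_PURIFICATION_TABLE = (
    ("crude", 153990.0, 177.0, 1.0, 100.0),
    ("ammonium sulphate precipitation", 13275.0, 351.0, 1.98, 8.62),
    ("dialysis", 5901.5, 825.0, 4.67, 3.83),
    ("DEAE-cellulose column", 3055.96, 2152.08, 12.15, 1.98),
)
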