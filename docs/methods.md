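# Methods

## Inactivation model and fitting

Thermal inactivation is treated as a single irreversible first-order
step, `A(t) = A(0)·exp(−Kd·t)`, at each temperature. `Kd` is estimated
by ordinary least squares of `ln(residual %)` on time (minutes). This
log-linear treatment — rather than nonlinear least squares on the
exponential itself — is the classical analysis that published
half-life/Arrhenius tables in enzymology are built on, and it is what
the bundled reference table is internally consistent with; a nonlinear
fit is available via `fit_first_order(..., method="nonlinear")` and
agrees exactly on noise-free data. Choices within the fit:

- The intercept is free, not forced through `ln(100)`: initial
  activities are often renormalized imperfectly.
- Points with residual ≤ 0 cannot enter a log fit; they are excluded
  and their indices recorded (`excluded_points`), never imputed. At
  least 3 positive-residual points are required.
- A non-positive decay slope (stable or activated enzyme) does not
  raise: the fit returns `kd ≤ 0`, an infinite half-life and a
  `non_decaying` flag, so condition screens do not abort.
- `t½ = ln2/Kd`; time is minutes and `Kd` min⁻¹ throughout.

## Arrhenius and Eyring treatment

One global OLS of `ln Kd` on `1/T` (K) gives `Ea = −R·slope`
(R = 8.314 J K⁻¹ mol⁻¹); per-temperature `Ea` is not estimated. The
shared `Ea` then feeds `ΔH(T) = Ea − RT`, which is affine in `T` with
slope exactly −R. `ΔG = −RT·ln(Kd·h/(kb·T))` uses h = 6.626×10⁻³⁴ J s
and kb = 1.3807×10⁻²³ J K⁻¹ (fixed at these conventional roundings on
purpose, for digit-level reproducibility of published tables).
`ΔS = (ΔH − ΔG)/T`, so `ΔS·T = ΔH − ΔG` holds row-wise to machine
precision by construction. Temperatures convert as `T(K) = T(°C) +
273.15` everywhere; Kelvin never appears in user-facing files.

### The Kd unit convention inside ΔG

Dimensional rigor wants `Kd` in s⁻¹ inside the Eyring logarithm, since
`kb·T/h` is a frequency in s⁻¹. Published thermostability tables,
however, conventionally insert the min⁻¹ number as-is, and the bundled
reference values reproduce only under that convention (e.g. ΔG =
102.79 kJ/mol at 80 °C from Kd = 46×10⁻⁴ min⁻¹; the s⁻¹ reading gives
≈114.8). The package therefore defaults to `kd_units="per_min"` and
offers `"per_sec"` for the SI-consistent variant, which shifts every
ΔG up by `R·T·ln 60` (≈12 kJ/mol at these temperatures). This non-SI
quirk is deliberate and documented rather than silently "corrected".

### Known inconsistencies in the bundled reference table

- Refitting the published, rounded Kd column (46, 57, 77, 99,
  138 ×10⁻⁴ min⁻¹) gives Ea ≈ 31.66 kJ/mol, not the published 31.102;
  the original fit evidently used unrounded constants. Consistency
  checks therefore allow 3% on Ea.
- The published ΔG at 100 °C (110.28) and 120 °C (111.66) disagree
  with the Eyring expression evaluated on their own row's Kd (≈107.18
  and ≈111.19). No guess is made about which number is the typo; those
  two rows are flagged (`LIPASE_DG_CONSISTENT_ROWS`) and excluded from
  strict assertions.
- Because `thermo_profile` derives ΔH from the refit Ea, its ΔH column
  sits ≈0.56 kJ/mol above the published one (which used Ea = 31.102);
  `enthalpy(31.102, T)` reproduces the published 28.16–27.83 range to
  0.01 kJ/mol.
- The published ΔS column is headed J/mol/K but its magnitudes
  (−0.211…−0.220) are kJ-scale; the package reports kJ/mol/K and
  labels it so.

## Activity units and purification accounting

One lipase unit is 1 μmol fatty acid released **per assay** (the fixed
incubation, 30 min by default), not per minute — the unit is defined
"under assay conditions" and no rate basis is invented; the incubation
time is carried for provenance only. Units = (V_test − V_blank) ×
M(NaOH) × 1000 / V_enzyme. A test titre below the blank clamps to 0
U/mL with a logged warning rather than going negative. Residual
activity is 100 × activity/reference and may exceed 100% (additive
activation). Percentages and all derived table quantities are computed
at full precision; 2-decimal rounding is applied only at report
display (`report.rounded`).

Purification ledgers require totals (mg protein, U activity) per step;
fold = specific activity / crude specific activity and yield = % of
crude total activity, both invariant under common rescaling of either
column. The bundled reference purification summary lists protein per
mL without volumes, so only its printed specific/total-activity
columns are reusable; the reference final-step fold prints as 12.15
where full-precision arithmetic gives 12.159 (truncation), hence 0.5%
tolerance on fold checks.

## Gel calibration

`log10(MW)` is fitted on Rf by OLS over ≥3 markers (base-10 is the
plotting convention; the base changes slope/intercept, not predicted
masses). A valid gel has Rf strictly decreasing with MW; violations
raise by default or warn in lenient mode. Estimates outside the marker
Rf range are extrapolations and are flagged with a warning — the
reliable regime is interpolation, as for a ~22 kDa band bracketed by
the 20.1 and 29.0 kDa standards. Measured Rf values for the reference
band are not available, so gel checks use exactly log-linear
constructed mappings, where `estimate_mw` must invert `calibrate` at
every marker.

## Synthetic-data generator

The generator emulates a thermostability study, not a mechanism. Rate
constants follow `kd(T) = kd_ref·exp[−Ea/R·(1/T − 1/T_ref)]`, so
`kd(T_ref) = kd_ref` exactly and no pre-exponential factor needs
choosing. Defaults mirror the reference study's conditions:
temperatures 80–120 °C in 10 °C steps, sampling every 30 min over 3 h
(7 points), `kd_ref = 46×10⁻⁴ min⁻¹` at 80 °C (t½ ≈ 150 min),
`Ea = 31.102 kJ/mol`, and 2% multiplicative noise — a realistic
titration CV. Noise is mean-1 lognormal (activities are positive and
titration error scales with signal); additive Gaussian is an option.
Stabilizers (divalent cations, polyols) are modeled as multiplicative
protection factors < 1 on `kd` — e.g. a factor of 150/180 reproduces a
150 → 180 min half-life extension — which captures their kinetic
effect but nothing of hydration-shell or ion-coordination mechanism,
concentration dependence, or the transient activity *increases* real
additives can cause. One global seed drives a splittable stream per
(temperature, condition) (`default_rng([seed, T, crc32(condition)])`),
so adding a condition never perturbs another's draws.

What passing the synthetic recovery tests shows: the estimator chain
(log-linear fit → Arrhenius OLS) is unbiased enough at these designs
to recover Ea to ~1.6% median error under 2% noise, and exactly
without noise. What it does not show: robustness to real-data
pathologies — biphasic decay, systematic baseline drift, or non-Arrhenius
curvature — which are outside the single-step model.

Ledger simulation inverts the accounting: given per-step activity
recoveries (fractions ≤ 1) and specific-activity gains (≥ 1), it
constructs protein/activity totals whose derived fold/yield reproduce
the chosen trajectory exactly.

## Problem sizes and numerics

Recovery statistics use 100 seeded replicates of the default 5 × 7
design, which characterizes the estimator's error distribution well at
negligible cost. OLS goes through `scipy.stats.linregress`; the
nonlinear option through `scipy.optimize.curve_fit` seeded from the
log-linear solution. Reports serialize to JSON at full precision, with
the timestamp isolated from equality so reruns on identical inputs
compare equal.

## Limitations

Single-exponential, irreversible inactivation only: no biphasic or
multi-state models, no melting-temperature/DSC/CD equilibrium
thermodynamics, no band detection from gel images, and no mechanistic
modeling of stabilizer chemistry. The Eyring ΔG carries the field's
min⁻¹ convention by default (see above) — compare across studies with
care.
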