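# thermokin

Analysis toolkit for enzyme thermostability studies: it turns
residual-activity time courses measured at a sweep of temperatures into
first-order inactivation constants, half-lives, an Arrhenius activation
energy, and Eyring denaturation thermodynamics, and it handles the
bookkeeping around such a study — titrimetric activity units,
purification fold/yield tables, and SDS-PAGE molecular-weight
calibration. It is written for enzymologists characterizing thermostable
enzymes (the bundled reference data are a hyperthermostable alkaline
lipase stable at 80–120 °C) and for anyone who wants those classical
calculations scripted, tested and reproducible instead of living in a
spreadsheet.

## The model

Irreversible thermal inactivation at constant temperature is first
order: residual activity decays as `A(t) = A(0)·exp(−Kd·t)`. The
denaturation constant `Kd` (min⁻¹) is the negative slope of an OLS fit
of `ln A` on `t`, and the half-life is `t½ = ln2/Kd`. Across
temperatures, `ln Kd` is fitted against `1/T` (K) to give the activation
energy of inactivation `Ea = −R·slope`. Transition-state parameters per
temperature follow the Eyring treatment:

```
ΔH = Ea − R·T
ΔG = −R·T · ln( Kd·h / (kb·T) )
ΔS = (ΔH − ΔG) / T
```

A synthetic-data generator produces Arrhenius-consistent studies
(configurable noise, stabilizer protection factors, designed
purification ledgers) with known ground truth, so the whole pipeline is
testable end to end.

## Worked example

`python examples/thermo_table.py` rebuilds the full denaturation table
from the bundled per-temperature rate constants of the reference
lipase:

```
Arrhenius fit: Ea = 31.660 kJ/mol  (r^2 = 0.9908)

 T(C)   Kd(1/min)  t1/2(min)  dH(kJ/mol)  dG(kJ/mol)  dS(kJ/mol/K)
   80     0.0046     150.68       28.72      102.79       -0.2097
   90     0.0057     121.60       28.64      105.14       -0.2106
  100     0.0077      90.02       28.56      107.18       -0.2107
  110     0.0099      70.01       28.47      109.34       -0.2111
  120     0.0138      50.23       28.39      111.19       -0.2106
```

A half-life of ~150 min at 80 °C falling to ~50 min at 120 °C, ΔG of
activation rising from 103 to 111 kJ/mol, and a small negative ΔS
describe an unusually thermostable enzyme. The other examples
(`fit_inactivation.py`, `simulate_and_recover.py`,
`purification_table.py`, `gel_calibration.py`, `titration_units.py`)
each exercise one capability the same way; `simulate_and_recover.py`
shows the pipeline recovering the true Ea with 1.6% median error from
noisy synthetic courses.

The same stages are available from a shell:

```
thermokin simulate --seed 1 --out courses.csv
thermokin fit-decay courses.csv --out fits.csv
thermokin thermo fits.csv --out table.csv
```

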