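"""Denaturation thermodynamics from per-temperature rate constants.

Uses the published Kd column of a hyperthermostable lipase (80-120 C)
to rebuild the full kinetic/thermodynamic table: half-lives, Arrhenius
activation energy, and per-temperature Eyring dH, dG, dS.
"""

from thermokin import thermo_profile
from thermokin.datasets import LIPASE_KD_TABLE

arr, profiles = thermo_profile(LIPASE_KD_TABLE)

print(f"Arrhenius fit: Ea = {arr.ea:.3f} kJ/mol  (r^2 = {arr.r_squared:.4f})\n")
print(" T(C)   Kd(1/min)  t1/2(min)  dH(kJ/mol)  dG(kJ/mol)  dS(kJ/mol/K)")
for p in profiles:
    print(
        f"{p.temperature_c:5.0f}  {p.kd:9.4f}  {p.t_half:9.2f}"
        f"  {p.dH:10.2f}  {p.dG:10.2f}  {p.dS:12.4f}"
    )

print(
    "\nEa is the Arrhenius energy barrier of inactivation; dG near 103-111\n"
    "kJ/mol with small, slightly negative dS indicates a thermodynamically\n"
    "stable enzyme whose unfolding transition state is compact."
)
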