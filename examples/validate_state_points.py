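"""Reduced state coordinates and density validation of simulated conditions.

Maps each stored state point to reduced coordinates (Tr = T/647.096 K,
Pr = P/220.64 bar), computes the percent deviation of simulated from
experimental density, and applies the 5% screening used to decide which
conditions are structurally trustworthy.
"""

from scwnet import (SIMULATION_CONDITIONS, density_percent_error,
                    reduced_state)

print("cond    Tr     Pr    density err (%)  keep(<=5%)")
kept = 0
for row in SIMULATION_CONDITIONS.itertuples():
    tr, pr = reduced_state(row.temperature_K, row.pressure_bar)
    err = density_percent_error(row.density_sim_kg_m3, row.density_exp_kg_m3)
    keep = err <= 5.0
    kept += keep
    print(f"{row.condition:>4}  {tr:5.2f}  {pr:5.2f}  {err:14.3f}  {keep}")
print(f"\n{kept} of {len(SIMULATION_CONDITIONS)} conditions pass the "
      "5% density-error screen")
# High-temperature/low-pressure points fail because the fluid is most
# compressible there, amplifying any model error in the simulated density.
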