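"""Flux balance analysis of a single growing cell.

Builds the bundled toy diazotroph cell (substrate catabolism, two terminal
oxidases, nitrogenase, amino-acid and PHB synthesis, biomass, fixed ATP
maintenance), pins substrate uptake, and maximizes growth.
"""

from xfba import ToySpec, make_toy_cell, solve_fba, toy_cell_max_growth

spec = ToySpec()
cell = make_toy_cell(spec)
substrate = 10.0  # mmol/gDW/h

sol = solve_fba(cell, fixed={"EX_s": -substrate})
print(f"status:            {sol.status}")
print(f"growth rate:       {sol.objective_value:.4f} 1/h")
print(f"closed form:       {toy_cell_max_growth(spec, substrate):.4f} 1/h")
print(f"O2 uptake:         {-sol.fluxes['EX_o2']:.3f} mmol/gDW/h")
print(f"NH3 uptake:        {-sol.fluxes['EX_nh3']:.3f} mmol/gDW/h")
print(f"CO2 release:       {sol.fluxes['EX_co2']:.3f} mmol/gDW/h")

# The LP optimum equals the analytic vertex (3*y_c*s - m)/(eff_atp + y_c*eff_c):
# growth is ATP-limited, with leftover carbon fully oxidized for extra ATP.
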