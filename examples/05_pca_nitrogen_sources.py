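"""PCA comparison of flux distributions across nitrogen regimes.

Community fluxes are summed over members (abundance-weighted) onto the
single-cell reaction index so all observations share one basis; PCA is
mean-centred only.  The first component separates the energetically expensive
N2-fixing states from growth on free ammonia.
"""

import numpy as np

from xfba import ToySpec, make_toy_cell, make_toy_community, solve_fba, solve_xfba
from xfba.scenarios import pca_flux_comparison, summed_member_fluxes

spec = ToySpec()
cell = make_toy_cell(spec, nitrogenase_open=True)
ref = list(cell.reactions)
obs = {}

sol = solve_fba(cell, fixed={"EX_s": -10.0})
obs["NH3"] = np.array([sol.fluxes[r] for r in ref])

closed = cell.copy()
closed.reactions["EX_nh3"].lower_bound = 0.0
sol = solve_fba(closed, fixed={"EX_s": -10.0})
obs["N2 (single cell)"] = np.array([sol.fluxes[r] for r in ref])

limited = cell.copy()
limited.reactions["EX_nh3"].lower_bound = -2.0
sol = solve_fba(limited, fixed={"EX_s": -10.0})
obs["NH3 (limited)"] = np.array([sol.fluxes[r] for r in ref])

comm, coupling = make_toy_community(spec)
csol = solve_xfba(comm, coupling, fixed={"EX_s[u]": -10.0})
obs["N2 (community)"] = summed_member_fluxes(csol, comm, ref)

res = pca_flux_comparison(obs)
print("explained variance fractions:",
      ", ".join(f"{v:.3f}" for v in res.explained_variance))
print("\nscores (PC1, PC2):")
for name, row in zip(res.observation_names, res.scores):
    print(f"  {name:<20} {row[0]:8.3f} {row[1]:8.3f}")
top = np.argsort(-np.abs(res.loadings[0]))[:5]
print("\nreactions loading strongest on PC1:")
for i in top:
    print(f"  {ref[i]:<10} {res.loadings[0][i]:+.3f}")
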