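"""Oxygen scan: feasibility threshold, growth optimum, cytochrome bd takeover.

Pins total community O2 uptake across a grid.  Below the threshold the pinned
substrate cannot be metabolized; on the rising branch the efficient
cytochrome c branch carries all oxygen and overflow carbon leaves as formate;
past the optimum the cell must scavenge excess O2 through the low-yield
cytochrome bd branch, and growth falls.
"""

import numpy as np

from xfba import ToySpec, make_toy_community
from xfba.scenarios import oxygen_cytochrome_scan

comm, coupling = make_toy_community(ToySpec())
grid = [9.0] + list(np.round(np.arange(10.0, 30.5, 2.0), 2))
res = oxygen_cytochrome_scan(
    comm, coupling, grid, "EX_o2[u]",
    cytc_ids={"m1": "CYTC[m1]", "m2": "CYTC[m2]"},
    cytbd_ids={"m1": "CYTBD[m1]", "m2": "CYTBD[m2]"},
    fixed={"EX_s[u]": -10.0}, nitrogenase_id="NASE[m2]")

print(f"{'O2':>5} {'status':>10} {'growth':>8} {'cyt c':>8} {'cyt bd':>8}")
for g, s in zip(res.grid, res.summaries):
    mu = s.get("community_growth")
    c = (s.get("m1.cytc") or 0) + (s.get("m2.cytc") or 0)
    bd = (s.get("m1.cytbd") or 0) + (s.get("m2.cytbd") or 0)
    print(f"{g['o2_uptake']:>5.1f} {s['status']:>10} "
          f"{'-' if mu is None else f'{mu:8.4f}'} {c:8.3f} {bd:8.3f}")

print(f"\nfeasibility threshold: {res.extras['feasibility_threshold']} "
      f"mmol O2/gDW/h  (minimum O2 to metabolize the pinned substrate)")
print(f"growth-maximizing O2:  {res.extras['optimal_o2']}")
print(f"bd activation onset:   {res.extras['bd_activation_onset']}")
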