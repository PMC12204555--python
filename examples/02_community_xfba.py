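"""XFBA on a two-member community: growing cells + non-growing N2 fixers.

Abundances are fixed at 0.9/0.1 and held constant over time by three linear
coupling rows (PHB top-up v_PHB = alpha*mu1*, member-2 accrual
mu2 = mu1* + MW*v_PHB/1000, and the abundance ratio mu2 = r*mu1) rather than
by assuming equal member growth rates.  N2 is the sole nitrogen source: the
non-growing member fixes it and feeds ammonia to the growing member through
the shared pool.
"""

from xfba import ToySpec, make_toy_community, member_phb_content, solve_xfba

comm, coupling = make_toy_community(ToySpec(), nongrowing_fraction=0.1)
sol = solve_xfba(comm, coupling, fixed={"EX_s[u]": -10.0},
                 nitrogenase_id="NASE[m2]")

m = sol.members
print(f"status:                 {sol.status}")
print(f"mu1  (growing):         {m['m1']['mu1']:.4f} 1/h")
print(f"mu1* (differentiation): {m['m1']['mu1_star']:.4f} 1/h")
print(f"mu2  (non-growing):     {m['m2']['mu2']:.4f} 1/h")
print(f"community growth:       {m['community']['community_growth']:.4f} 1/h")
print(f"N2 fixation:            {m['m2']['n2_fixation']:.4f} mmol/gDW/h")
print(f"NH3 to growing member:  {m['m2']['export_nh3']:.4f} mmol/gDW/h")
content = member_phb_content(sol, coupling, comm)
print(f"PHB content growing:    {content['m1']:.1%}")
print(f"PHB content non-growing:{content['m2']:.1%}")

# The coupling makes mu1*/mu1 equal r/(1 + alpha*MW/1000) and pushes the
# non-growing PHB mass fraction to exactly 50 %; community growth is lower
# than on ammonia because every fixed NH3 costs 8 ATP.
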