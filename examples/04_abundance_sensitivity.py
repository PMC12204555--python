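"""Sensitivity of the community to the non-growing member's abundance.

Rebuilds the community for non-growing fractions of 5-30 %, recomputing the
abundance ratio r = f/(1-f) and the differentiation coefficient each time.
More N2 fixers means more substrate diverted to fixation and PHB storage:
the growing member's rate and total N2 fixation both fall.
"""

from xfba import ToySpec, make_toy_community, make_toy_members
from xfba.scenarios import abundance_sensitivity
from xfba.toys import configure_toy_boundaries

spec = ToySpec()
_, coupling = make_toy_community(spec)
res = abundance_sensitivity(
    make_toy_members(spec), coupling,
    [0.05, 0.10, 0.15, 0.20, 0.25, 0.30],
    fixed={"EX_s[u]": -10.0}, nitrogenase_id="NASE[m2]",
    community_setup=configure_toy_boundaries)

print(f"{'f':>5} {'r':>7} {'mu1':>8} {'mu1*':>8} {'mu2':>8} "
      f"{'N2 fix':>8} {'total':>8}")
for g, s in zip(res.grid, res.summaries):
    print(f"{g['nongrowing_fraction']:>5.2f} {g['r']:>7.4f} "
          f"{s['m1.mu1']:>8.4f} {s['m1.mu1_star']:>8.4f} "
          f"{s['m2.mu2']:>8.4f} {s['m2.n2_fixation']:>8.4f} "
          f"{s['community_growth']:>8.4f}")

first, last = res.summaries[0], res.summaries[-1]
print(f"\nmu1 change 5% -> 30%:       "
      f"{(last['m1.mu1']/first['m1.mu1'] - 1):+.1%}")
print(f"N2 fixation change 5% -> 30%: "
      f"{(last['m2.n2_fixation']/first['m2.n2_fixation'] - 1):+.1%}")
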