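# Methods

## The modelling problem

Free-living diazotroph populations face an oxygen paradox: nitrogenase needs
large amounts of ATP (8 mol ATP per mol NH₃ fixed, 16 per N₂), which aerobes
generate by respiration, yet the enzyme is inactivated by oxygen. One
resolution is division of labour: a minority of cells differentiates into
non-growing N₂ fixers (high PHB content, respiratory protection via the
low-efficiency cytochrome *bd* oxidase) while the majority grows on the
ammonia they release. The population then behaves like a two-member
community with a roughly constant member ratio even though one member does
not grow at all — a regime the equal-growth community FBA frameworks (cFBA,
SteadyCom) cannot represent.

## XFBA formulation

Let the community have members m = 1..M with abundance fractions X_m > 0,
ΣX_m = 1, a merged stoichiometric matrix S over member-tagged metabolites
plus a shared extracellular pool `[u]`, and flux vector v on a
per-gram-member basis. XFBA solves

    max  c'v   s.t.   S_x v = 0,  lb ≤ v ≤ ub,  coupling rows,

where S_x = S·X and X is block-diagonal: member m's columns are scaled by
X_m, and the community exchange columns (reactions touching only `[u]`
species) form an identity block. Mass balances, including those on the
shared pool, are therefore written on aggregate (community-basis) rates
X_m·v while bounds act on member-specific fluxes. Because the abundances
are fixed numbers the problem stays a linear program.

For the growing/non-growing split the growing member carries two copies of
its biomass reaction — growth (μ₁) and differentiation into the non-growing
state (μ₁\*) — and the non-growing member carries a PHB accumulation flux
v_PHB but no biomass reaction. μ₂, the non-growing biomass accrual rate, is
an accounting variable (a defined linear expression, not a network column).
On the community basis:

    v_PHB = α μ₁*                         (1)
    μ₂   = μ₁* + MW_PHB v_PHB / 1000      (2)
    μ₂   = r μ₁,   r = X₂/X₁              (3)

Eq. (2) says non-growing biomass accrues as differentiated cells plus the
mass of the PHB they take up; Eq. (3) keeps dB₂/dB₁ equal to B₂/B₁, i.e.
the abundances constant over time. Substituting (1)–(2) into (3) gives the
differentiation coefficient

    μ₁* = c μ₁,   c = r / (1 + α MW_PHB/1000).

Maximizing μ₁ is the objective; with (3) active, μ₁ + μ₂ = (1+r) μ₁, so the
total community growth is maximized simultaneously.

### The PHB top-up coefficient α

Differentiated biomass arrives carrying the growing cells' PHB mass fraction
p_base and must end at the non-growing target p_target. The package defines

    α = 1000 (p_target − p_base) / p_target / MW_PHB   [mmol/gDW],

i.e. the mass deficit divided by the *target* fraction. The realized content
of the accrued non-growing biomass is, from (1)–(2),

    content = (p_base + a) / (1 + a),   a = α MW_PHB / 1000,

which equals p_target exactly when p_target = 1/2 — the study condition
(p_base = 0.159, p_target = 0.50, MW_PHB = 86 g/mol, α = 7.9303). For other
targets the identity above is what holds; a coefficient exact for arbitrary
targets would divide the deficit by (1 − p_target) instead. The default
keeps the 50 %-exact definition because that is the condition the
coefficient was defined for; `member_phb_content` always reports the
realized content rather than assuming the target. MW_PHB defaults to
86.0 g/mol (the value α = 7.9303 back-calculates to, rather than the exact
residue mass 86.09) and is exposed as a parameter.

## Model container and community construction

Models are plain containers (metabolites, reactions with signed
stoichiometries and bounds, an objective id); compartments are bracketed id
suffixes (`[c]`, `[e]`, shared `[u]`, member tags `[m1]`). `build_community`
duplicates each member under its tag, creates one pooled `[u]` species per
shared extracellular metabolite, connects it with reversible per-member
transports `TU_<base>[<member>]`, and replaces the members' own exchanges of
shared species with a single community exchange whose bounds are the widest
of the member bounds. Abundance scaling is applied to the merged
coefficients (`CommunityModel.scaled_model()`); `abundance_scale` performs
the same operation on an explicit matrix and rejects unassigned columns.

Conventions, all following common constraint-based practice: exchange flux
> 0 is secretion and uptake enters as a negative bound; "fixed" uptakes are
equality pins (lb = ub); ATPM (maintenance) bounds are member-level (per
gram member biomass) before scaling — community-basis values can be encoded
by dividing by the member abundance. Pins on community exchange reactions
are community-basis by construction, since those columns are unscaled.

## Solving

LPs are built and solved through cobrapy/optlang with the GLPK backend
(feasibility/optimality tolerances 1e-9). Because community optima are
routinely degenerate (the amino-acid exchange experiments exist precisely to
show this), reported flux distributions are made reproducible by a
parsimonious second stage: the objective is pinned at its optimum and total
absolute flux is minimized. Objective values are solver-grade reproducible
(1e-6 relative); individual fluxes are only meaningful together with FVA
widths, and `flux_variability` is the instrument for any claim about
alternative optima. `min_exchange_for_feasibility` locates feasibility
boundaries by an LP minimization of the exchange flux followed by a
bisection confirmation on equality pins, reported at 0.01 resolution.
Infeasible and unbounded solves are returned as statuses, never raised, and
scans record infeasible grid points instead of skipping them.

## Biomass construction

`build_biomass_reaction` converts a macromolecular composition
(macromolecule mass fractions in w/w %, each split into monomers with molar
masses) into coefficients −1000·(pct/100)·within/MW mmol/gDW, so one unit of
biomass flux consumes exactly 1 g of monomers (mass closure asserted to
1e-3). Polymerization water/ATP costs are excluded by default — the optional
`ggr` field adds growth-associated ATP hydrolysis. The shipped composition
file carries the eight rhizobial macromolecule fractions (protein 50.1,
DNA 3.0, RNA 8.5, phospholipids 0.9, peptidoglycan 2.5,
lipopolysaccharides 3.4, polysaccharides 15.7, PHB 15.9 w/w %); the monomer
splits under each macromolecule are synthetic single-representative
placeholders, because only the fractions are published — mass closure holds
regardless of the placeholder molar masses, but monomer-level coefficients
from the default file should not be over-interpreted.

`find_dead_ends` flags metabolites lacking a producer or a consumer,
counting a reversible reaction as both for every species it touches — the
case that naive directional scans miss. Detection only; no automated
gap filling.

## The toy fixture

The toy cell is the smallest network exercising every structural feature the
method needs: substrate catabolism into quinol and a carbon precursor, full
precursor oxidation, cytochrome *c* and *bd* branches (4 vs 2 ATP per O₂ —
*bd* burns twice the oxygen per ATP), nitrogenase (16 ATP per N₂ → 2 NH₃),
amino-acid synthesis/degradation, PHB synthesis, a formate overflow, biomass
(10 ATP + 2 NH₃ + 2 precursor + 1 amino acid per gram) and a fixed ATP
maintenance drain. Stoichiometries are small integers so optima are exact
rationals:

    single cell:   μ = (3 y_c s − m) / (eff_atp + y_c eff_c)
    community (α=0): μ₁ = (3 y_c S − X₁m₁ − X₂m₂)
                          / (X₁(1+r)(eff_atp + y_c eff_c + a_n eff_n))

with y_c the cytochrome-c ATP yield per O₂, a_n the nitrogenase ATP cost per
NH₃ and eff_* the biomass demands including the in-member amino-acid
synthesis. Two design points matter: the amino acid makes inter-member
exchange *redundant* rather than useless (shipping preformed amino acid
substitutes in-member synthesis at identical marginal cost), which is what
produces the plateau in exchange-robustness scans; and the formate overflow
provides a redox-free carbon exit, which is what creates the rising branch
of the oxygen scan (below the growth optimum, spare carbon leaves as formate
instead of demanding oxygen). Seeds perturb only bounds (the substrate
limit), never stoichiometry, so the closed forms stay valid. The toy's
feasibility threshold under pinned substrate is exactly one O₂ per substrate
(the quinol from catabolism must be respired), and past the growth optimum
the LP shifts oxidase flux from *c* to *bd* because pinned O₂ must be
consumed while ATP production is capped by demand.

What the toy does not emulate: genome-scale redundancy (hundreds of
alternative pathways), realistic P/O ratios and proton accounting, nitrite
and nitrate assimilation, element-balanced stoichiometries, or any kinetic
oxygen inhibition of nitrogenase (which member scavenges excess O₂ is
therefore degenerate in the toy, and the oxygen-scan activation window is
reported at the community level). Tests passing on the toy establish the
correctness of the formulation and the solver plumbing, not quantitative
claims about the organism; the genome-scale reproductions additionally
require the original supplementary models under `data/supplementary/`.

## Scenario battery

* **C/N-source screen** — uptake of each carbon source is pinned at the rate
  supplying the same C-atom flux as the reference (succinate at
  4.16 mmol/gDW/h, 4 carbons: glucose 2.773, glutamine 3.328), the nitrogen
  source is opened, growth maximized; for a combined C&N source the ammonia
  exchange stays free in both directions so excess nitrogen can be excreted.
* **Exchange robustness** — the community-basis inter-member transfer of one
  shared metabolite is pinned across a grid spanning both directions
  (negative = non-growing → growing) and XFBA re-solved; the base optimum
  bounds every pinned optimum because pinning only restricts the feasible
  set.
* **Abundance sensitivity** — the community is rebuilt per non-growing
  fraction f ∈ {5..30 %} with r = f/(1−f) ∈ {1/19, 1/9, 3/17, 1/4, 1/3,
  3/7} and c recomputed.
* **Oxygen scan** — total community O₂ uptake pinned across a grid (default
  resolution 0.05 with 0.01 boundary refinement); reports growth, per-member
  oxidase fluxes, the feasibility threshold, the growth-maximizing O₂ and
  the *bd* activation window. With O₂ as an allowance (upper bound) instead
  of a pin the response is monotone non-decreasing; the rise-and-fall
  appears only under equality pinning.
* **PCA** — flux vectors are collapsed onto the single-cell reaction index
  (members summed on the community basis, community exchanges mapped to
  their single-model counterparts), then mean-centred PCA; no unit-variance
  scaling, since fluxes share units and scaling would distort pathway
  dominance (recorded in `PCAResult.preprocessing`). With k observations at
  most k−1 components carry variance; identical observations are reported
  as degenerate rather than normalized.

Percent-change readouts quote endpoint grid values. "N₂ fixation" is the
nitrogenase flux of the non-growing member on the community basis.

## Numerical choices and degenerate inputs

Default bounds where a source omits them: (0, 1000) irreversible,
(−1000, 1000) reversible, mmol/gDW/h. Coefficients serialize with
round-trip-exact floats. Zero-abundance members must be removed, not
zeroed (the scaling would silently delete their constraints). μ₂ = 0 makes
the non-growing PHB content undefined and it is reported as such. An empty
model yields a 0×0 matrix; empty reaction tables are format errors. The
formula grammar accepts `->`, `=>`, `<->`, `<=>` with exactly one arrow and
either side empty.

## Problem sizes used in the shipped runs

The test suite and example scripts run entirely on the toy fixture
(single cell ≈ 30 reactions; community ≈ 55 reactions, one auxiliary
variable, three coupling rows) with oxygen grids of ≈ 20 points and
6-point abundance grids — sizes chosen so every optimum has an independent
dense-LP or closed-form cross-check. The same code paths take genome-scale
models (hundreds to ~1000 reactions) without modification.

## Known limitations

Two-member communities are the tested regime (the generic code allows more
members, but coupling rows are defined for the growing/non-growing pair).
No MILP/loopless FBA, thermodynamic constraints or dynamic FBA. SBML is not
read or written. Gap *filling* is out of scope. The XLSX reader tolerates
header variants but will refuse rather than guess when mandatory columns
are missing.
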