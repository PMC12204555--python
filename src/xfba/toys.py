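"""Small fully-specified toy models with analytically known optima.

The toy cell mirrors the structural features the method exercises in a real
diazotroph network: a single carbon substrate split into redox (quinol) and a
carbon precursor, two terminal oxidases with different ATP yields per O2
(cytochrome c high, cytochrome bd low — bd burns more O2 per ATP), an
ATP-expensive nitrogenase, ammonia assimilation into an amino acid and
biomass, PHB synthesis, and a fixed ATP maintenance drain.  Stoichiometries
are small integers so the optima are exact rationals with closed forms in the
parameters.

Network (member basis, mmol/gDW/h):

    CAT:    s -> 2 qh2 + 2 cpre             (catabolism)
    OXC:    cpre -> 2 qh2 + co2             (full oxidation of the precursor)
    CYTC:   2 qh2 + o2 -> y_c atp           (cytochrome c branch, lumped with
                                             ATP synthase)
    CYTBD:  2 qh2 + o2 -> y_bd atp          (cytochrome bd branch, y_bd < y_c)
    NASE:   n2 + 2*a_n atp -> 2 nh3         (nitrogenase, a_n ATP per NH3)
    ASPS:   cpre + nh3 + atp -> asp         (amino-acid synthesis)
    ASPD:   asp -> cpre + nh3               (amino-acid catabolism)
    FORM:   cpre -> for                     (formate overflow, no redox)
    PHBS:   cpre + atp -> phb
    BIOMASS: b_atp atp + b_n nh3 + b_c cpre + b_a asp ->   (growth, 1/h)
    ATPM:   atp ->                           (fixed maintenance, lb = ub)

With ample O2 and NH3 and the substrate pinned at s, the optimum fully
oxidizes the leftover precursor and synthesizes its own amino acid, giving

    mu_max = (3 y_c s - m) / ((b_atp + b_a) + y_c (b_c + b_a)).

The amino acid makes inter-member exchange redundant rather than useless:
shipping preformed asp between members substitutes in-member synthesis at
identical marginal cost, which is what produces the plateau in exchange
robustness scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import (
    AbundanceVector,
    CommunityModel,
    CouplingSpec,
    build_community,
)
from .model import MetabolicModel, Reaction, parse_reaction_formula
from .network import compute_alpha

__all__ = [
    "ToySpec",
    "make_toy_cell",
    "make_toy_members",
    "configure_toy_boundaries",
    "make_toy_community",
    "toy_cell_max_growth",
    "toy_community_max_growth",
]


@dataclass
class ToySpec:
    """Parameters of the toy network (all yields positive; the bd branch must
    yield strictly less ATP per O2 than the c branch)."""

    atp_per_o2_cytc: float = 4.0
    atp_per_o2_cytbd: float = 2.0
    atp_per_nh3_nitrogenase: float = 8.0
    biomass_atp: float = 10.0
    biomass_nh3: float = 2.0
    biomass_cpre: float = 2.0
    biomass_asp: float = 1.0
    atpm: float = 1.0
    atpm_nongrowing: float = 2.0
    substrate_uptake: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.atp_per_o2_cytc, self.atp_per_o2_cytbd,
               self.atp_per_nh3_nitrogenase, self.biomass_atp) <= 0:
            raise ValueError("all yields must be positive")
        if self.atp_per_o2_cytbd >= self.atp_per_o2_cytc:
            raise ValueError(
                "cytochrome bd must yield less ATP per O2 than cytochrome c"
            )

    # effective per-biomass demands once the amino acid is synthesized in-member
    @property
    def eff_atp(self) -> float:
        return self.biomass_atp + self.biomass_asp

    @property
    def eff_cpre(self) -> float:
        return self.biomass_cpre + self.biomass_asp

    @property
    def eff_nh3(self) -> float:
        return self.biomass_nh3 + self.biomass_asp


def _add(model: MetabolicModel, rxn_id: str, formula: str,
         lb: float | None = None, ub: float = 1000.0, name: str = "") -> None:
    stoich, reversible = parse_reaction_formula(formula)
    if lb is None:
        lb = -1000.0 if reversible else 0.0
    model.add_reaction(
        Reaction(id=rxn_id, stoichiometry=stoich, lower_bound=lb,
                 upper_bound=ub, name=name)
    )


def make_toy_cell(
    spec: ToySpec | None = None,
    model_id: str = "toy_cell",
    nitrogenase_open: bool = False,
    with_biomass: bool = True,
) -> MetabolicModel:
    """Build the toy cell.  Exchanges default to: substrate/O2/NH3/N2 uptake
    open, CO2 secretion open, PHB and amino-acid exchange closed.  Seeded
    specs perturb only bounds (the substrate uptake limit), never
    stoichiometry, so the closed forms stay valid."""
    spec = spec or ToySpec()
    s_max = spec.substrate_uptake
    if spec.seed is not None:
        rng = np.random.default_rng(spec.seed)
        s_max = float(s_max * rng.uniform(0.5, 1.5))
    m = MetabolicModel(id=model_id)
    y_c = spec.atp_per_o2_cytc
    y_bd = spec.atp_per_o2_cytbd
    a_n2 = 2.0 * spec.atp_per_nh3_nitrogenase

    _add(m, "CAT", "s[c] -> 2 qh2[c] + 2 cpre[c]", name="catabolism")
    _add(m, "OXC", "cpre[c] -> 2 qh2[c] + co2[c]", name="precursor oxidation")
    _add(m, "CYTC", f"2 qh2[c] + o2[c] -> {y_c} atp[c]", name="cytochrome c branch")
    _add(m, "CYTBD", f"2 qh2[c] + o2[c] -> {y_bd} atp[c]",
         name="cytochrome bd branch")
    _add(m, "NASE", f"n2[c] + {a_n2} atp[c] -> 2 nh3[c]", name="nitrogenase",
         ub=1000.0 if nitrogenase_open else 0.0)
    _add(m, "ASPS", "cpre[c] + nh3[c] + atp[c] -> asp[c]",
         name="amino-acid synthesis")
    _add(m, "ASPD", "asp[c] -> cpre[c] + nh3[c]", name="amino-acid catabolism")
    _add(m, "FORM", "cpre[c] -> for[c]", name="formate overflow")
    _add(m, "PHBS", "cpre[c] + atp[c] -> phb[c]", name="PHB synthesis")
    if with_biomass:
        _add(
            m, "BIOMASS",
            f"{spec.biomass_atp} atp[c] + {spec.biomass_nh3} nh3[c] + "
            f"{spec.biomass_cpre} cpre[c] + {spec.biomass_asp} asp[c] -> ",
            name="biomass",
        )
    _add(m, "ATPM", "atp[c] -> ", lb=spec.atpm, ub=spec.atpm, name="maintenance")

    for base, (lb, ub) in {
        "s": (-s_max, 0.0), "o2": (-1000.0, 0.0), "nh3": (-1000.0, 1000.0),
        "n2": (-1000.0, 0.0), "co2": (0.0, 1000.0), "for": (0.0, 1000.0),
        "phb": (0.0, 0.0), "asp": (0.0, 0.0),
    }.items():
        _add(m, f"T_{base}", f"{base}[c] <=> {base}[e]", name=f"{base} transport")
        _add(m, f"EX_{base}", f"{base}[e] -> ", lb=lb, ub=ub,
             name=f"{base} exchange")
    m.objective = "BIOMASS" if with_biomass else None
    m.validate()
    return m


def toy_cell_max_growth(spec: ToySpec, substrate: float) -> float:
    """Closed-form FBA optimum of the toy cell with the substrate pinned and
    ample O2 and NH3 (see module docstring for the derivation)."""
    y_c = spec.atp_per_o2_cytc
    return (3.0 * y_c * substrate - spec.atpm) / (
        spec.eff_atp + y_c * spec.eff_cpre
    )


def make_toy_members(spec: ToySpec | None = None) -> list[tuple[str, MetabolicModel]]:
    """The two community members: growing cells ``m1`` (nitrogenase closed,
    two biomass copies for growth and differentiation) and non-growing N2
    fixers ``m2`` (no biomass reaction, nitrogenase open, PHB export open)."""
    spec = spec or ToySpec()
    m1 = make_toy_cell(spec, model_id="toy_growing", nitrogenase_open=False)
    diff = m1.reactions["BIOMASS"].copy()
    diff.id, diff.name = "BIOMASS_DIFF", "differentiation to non-growing"
    m1.add_reaction(diff)

    m2_spec = ToySpec(**{**spec.__dict__, "atpm": spec.atpm_nongrowing})
    m2 = make_toy_cell(m2_spec, model_id="toy_fixer", nitrogenase_open=True,
                       with_biomass=False)
    m2.reactions["T_phb"].lower_bound = 0.0
    m2.reactions["T_phb"].upper_bound = 1000.0
    m2.reactions["EX_phb"].upper_bound = 1000.0
    return [("m1", m1), ("m2", m2)]


def configure_toy_boundaries(community: CommunityModel) -> None:
    """Community boundary for the N2-fixing scenario: NH3 uptake closed (N2 is
    the sole N source), PHB accrues through the non-growing member only, the
    amino acid circulates between members but cannot cross the boundary."""
    merged = community.merged
    merged.reactions["EX_nh3[u]"].lower_bound = 0.0
    merged.reactions["EX_phb[u]"].lower_bound = 0.0
    merged.reactions["EX_phb[u]"].upper_bound = 1000.0
    merged.reactions["EX_asp[u]"].lower_bound = 0.0
    merged.reactions["EX_asp[u]"].upper_bound = 0.0
    merged.reactions["T_phb[m1]"].upper_bound = 0.0
    merged.reactions["T_phb[m1]"].lower_bound = 0.0
    # community substrate uptake pinned by callers; default widest bounds
    merged.reactions["EX_s[u]"].lower_bound = -1000.0


def make_toy_community(
    spec: ToySpec | None = None,
    nongrowing_fraction: float = 0.1,
    alpha: float | None = None,
    p_base: float = 0.159,
    p_target: float = 0.50,
    mw_phb: float = 86.0,
) -> tuple[CommunityModel, CouplingSpec]:
    """Two-member toy community (see :func:`make_toy_members`), all
    extracellular species shared through [u] and the boundary configured for
    growth on N2 (:func:`configure_toy_boundaries`).  ``alpha`` defaults to
    ``compute_alpha(p_base, p_target, mw_phb)``.
    """
    spec = spec or ToySpec()
    f = nongrowing_fraction
    if not 0.0 < f < 1.0:
        raise ValueError("nongrowing_fraction must lie in (0, 1)")
    if alpha is None:
        alpha = compute_alpha(p_base, p_target, mw_phb)

    community = build_community(
        make_toy_members(spec),
        AbundanceVector({"m1": 1.0 - f, "m2": f}),
        shared="all-extracellular",
        community_id="toy_community",
    )
    configure_toy_boundaries(community)
    coupling = CouplingSpec(
        r=f / (1.0 - f), alpha=alpha, mw_phb=mw_phb, p_base=p_base,
        growth_id="BIOMASS[m1]", diff_id="BIOMASS_DIFF[m1]",
        phb_flux_id="T_phb[m2]",
    )
    return community, coupling


def toy_community_max_growth(
    spec: ToySpec, substrate: float, nongrowing_fraction: float
) -> float:
    """Closed-form XFBA optimum (alpha = 0) for the toy community: the
    growing member's specific growth rate.

    With the member ATP and carbon balances and the community substrate and
    NH3 balances all tight,

        mu1_spec = (3 y_c S - x1 m1 - x2 m2)
                   / (x1 (1+r) (eff_atp + y_c eff_cpre + a_n eff_nh3)).
    """
    f = nongrowing_fraction
    x1, x2 = 1.0 - f, f
    r = x2 / x1
    y_c = spec.atp_per_o2_cytc
    denom = x1 * (1.0 + r) * (
        spec.eff_atp
        + y_c * spec.eff_cpre
        + spec.atp_per_nh3_nitrogenase * spec.eff_nh3
    )
    return (
        3.0 * y_c * substrate - x1 * spec.atpm - x2 * spec.atpm_nongrowing
    ) / denom
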