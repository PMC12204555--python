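"""Two-member community construction and XFBA.

XFBA extends FBA to a community with *fixed* member abundances but *unequal*
member growth rates.  The community stoichiometric matrix is abundance-scaled,
``S_x = S . X``, where X is block-diagonal: each member's columns are
multiplied by that member's abundance fraction and the shared-compartment
exchange columns form an identity block.  Fluxes therefore stay on a
per-gram-member basis while mass balances are written on aggregate
(community-basis) rates.

For a population of growing cells (member 1) feeding on ammonia fixed by
differentiated non-growing N2-fixing cells (member 2), three coupling rows
keep the abundances constant over time without assuming equal growth:

* PHB top-up:       v_PHB = alpha * mu1_star
* member-2 accrual: mu2 = mu1_star + MW_PHB * v_PHB / 1000
* fixed abundances: mu2 = r * mu1,  r = X2/X1

with mu1 the growing member's (aggregate) growth rate, mu1_star the
differentiation rate (a second copy of the biomass reaction), v_PHB the
non-growing member's PHB accumulation flux, and alpha the extra PHB (mmol per
gram differentiated biomass) that raises the PHB mass fraction from the
growing cells' base value to the non-growing cells' target.  Substituting the
first two rows into the third gives the differentiation coefficient
``mu1_star = c * mu1`` with ``c = r / (1 + alpha*MW_PHB/1000)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .fba import (
    FEASIBILITY_TOL,
    FluxSolution,
    _apply_pins,
    _solve,
    to_cobra,
)
from .model import MetabolicModel, Metabolite, Reaction, split_compartment
from .network import StoichiometricMatrix, build_stoichiometric_matrix

__all__ = [
    "AbundanceVector",
    "CouplingSpec",
    "CommunityModel",
    "CommunityBuildError",
    "build_community",
    "abundance_scale",
    "differentiation_coefficient",
    "add_coupling_constraints",
    "solve_xfba",
    "member_phb_content",
]

SHARED = "u"  # shared-compartment tag


class CommunityBuildError(ValueError):
    pass


@dataclass
class AbundanceVector:
    """Member tag -> abundance fraction; strictly positive, summing to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for tag, x in self.fractions.items():
            if x <= 0:
                raise ValueError(
                    f"abundance of {tag!r} must be strictly positive (remove "
                    f"zero-abundance members instead of zeroing them)"
                )
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total!r}, expected 1")

    def __getitem__(self, tag: str) -> float:
        return self.fractions[tag]

    def items(self):
        return self.fractions.items()


@dataclass
class CouplingSpec:
    """Parameters of the growth/differentiation/PHB coupling.

    ``r`` is the abundance ratio member2/member1; ``alpha`` the PHB top-up in
    mmol per gram of differentiated biomass; ``growth_id``/``diff_id`` the two
    biomass-reaction copies of member 1; ``phb_flux_id`` the non-growing
    member's PHB accumulation flux; ``p_base`` the growing cells' PHB mass
    fraction (used for content accounting).
    """

    r: float
    alpha: float
    growth_id: str
    diff_id: str
    phb_flux_id: str
    mw_phb: float = 86.0
    p_base: float = 0.159

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("abundance ratio r must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.mw_phb <= 0:
            raise ValueError("mw_phb must be positive")


def differentiation_coefficient(spec: CouplingSpec) -> float:
    """c such that mu1_star = c * mu1 in every coupled solution."""
    return spec.r / (1.0 + spec.alpha * spec.mw_phb / 1000.0)


@dataclass
class CommunityModel:
    """Member-tagged merged network with a shared compartment.

    ``merged`` holds the *unscaled* union (member reactions tagged, shared
    species in ``[u]``); ``scaled_model()`` applies the abundance scaling and
    is what XFBA solves.
    """

    id: str
    members: list[tuple[str, MetabolicModel]]
    abundances: AbundanceVector
    merged: MetabolicModel
    shared_ids: list[str]
    exchange_ids: list[str]  # unscaled identity block (community exchanges)
    transport_ids: dict[str, dict[str, str]] = field(default_factory=dict)
    # transport_ids[base_id][member] = transport reaction id ([c]/[e] -> [u])

    def member_of(self, rxn_id: str) -> str | None:
        return self.merged.reactions[rxn_id].member

    def scaled_model(self) -> MetabolicModel:
        """Apply S_x = S.X: member columns scaled by abundance, community
        exchange columns untouched."""
        scaled = self.merged.copy()
        for rxn in scaled.reactions.values():
            if rxn.member is not None:
                x = self.abundances[rxn.member]
                rxn.stoichiometry = {m: c * x for m, c in rxn.stoichiometry.items()}
        return scaled

    def scaled_matrix(self) -> StoichiometricMatrix:
        S = build_stoichiometric_matrix(self.merged)
        column_members = {
            rid: r.member for rid, r in self.merged.reactions.items()
        }
        return abundance_scale(S, self.abundances, self.exchange_ids, column_members)

    def aggregate(self, fluxes: Mapping[str, float], rxn_id: str) -> float:
        """Community-basis flux of a reaction (abundance-weighted for member
        reactions, as-is for the exchange block)."""
        member = self.merged.reactions[rxn_id].member
        v = fluxes.get(rxn_id, 0.0)
        return v * self.abundances[member] if member is not None else v


def _tag_met(met_id: str, member: str) -> str:
    return f"{met_id}[{member}]"


def _tag_rxn(rxn_id: str, member: str) -> str:
    return f"{rxn_id}[{member}]"


def build_community(
    members: Sequence[tuple[str, MetabolicModel]],
    abundances: AbundanceVector | dict[str, float],
    shared: Iterable[str] | str = "all-extracellular",
    community_id: str = "community",
) -> CommunityModel:
    """Merge member models into a compartmentalized community.

    Each member's reactions and metabolites are duplicated under its tag.
    Every shared species (given as base ids without compartment, or
    ``"all-extracellular"`` for every extracellular species of any member)
    gets one pooled metabolite in ``[u]``, per-member transport reactions
    ``TU_<base>[<member>]`` (member's extracellular copy <-> pool, reversible)
    and one community exchange ``EX_<base>[u]``; the members' own exchange
    reactions for shared species are dropped in favour of the community
    exchange, whose bounds are the widest of the member bounds.
    """
    if isinstance(abundances, dict):
        abundances = AbundanceVector(abundances)
    tags = [tag for tag, _ in members]
    if sorted(tags) != sorted(abundances.fractions):
        raise CommunityBuildError(
            f"abundance tags {sorted(abundances.fractions)} do not match member "
            f"tags {sorted(tags)}"
        )

    if isinstance(shared, str):
        if shared != "all-extracellular":
            raise CommunityBuildError(f"unknown shared-species selector {shared!r}")
        shared_ids = sorted(
            {
                split_compartment(m.id)[0]
                for _, model in members
                for m in model.metabolites.values()
                if split_compartment(m.id)[1] == "e"
            }
        )
    else:
        shared_ids = list(shared)

    merged = MetabolicModel(id=community_id)
    transport_ids: dict[str, dict[str, str]] = {b: {} for b in shared_ids}
    exchange_bounds: dict[str, list[float]] = {}

    for tag, model in members:
        ext_bases = {
            split_compartment(m.id)[0]
            for m in model.metabolites.values()
            if split_compartment(m.id)[1] == "e"
        }
        for base in shared_ids:
            if base in ext_bases:
                continue
            # only an error if this member was explicitly asked to share it
            if not isinstance(shared, str):
                raise CommunityBuildError(
                    f"shared species {base!r} has no extracellular form in "
                    f"member {tag!r}"
                )
        for m in model.metabolites.values():
            merged.add_metabolite(
                Metabolite(
                    id=_tag_met(m.id, tag), name=m.name,
                    compartment=m.compartment, formula=m.formula, member=tag,
                )
            )
        for r in model.reactions.values():
            base_met = next(iter(r.stoichiometry))
            base_id, comp = split_compartment(base_met)
            if r.is_exchange(("e",)) and base_id in transport_ids:
                # member exchange of a shared species -> community exchange
                lo, hi = exchange_bounds.get(base_id, [math.inf, -math.inf])
                exchange_bounds[base_id] = [
                    min(lo, r.lower_bound), max(hi, r.upper_bound)
                ]
                continue
            merged.add_reaction(
                Reaction(
                    id=_tag_rxn(r.id, tag),
                    stoichiometry={
                        _tag_met(m, tag): c for m, c in r.stoichiometry.items()
                    },
                    lower_bound=r.lower_bound, upper_bound=r.upper_bound,
                    name=r.name, subsystem=r.subsystem, member=tag,
                )
            )
        for base in shared_ids:
            if base not in ext_bases:
                continue
            pool = f"{base}[{SHARED}]"
            if pool not in merged.metabolites:
                merged.add_metabolite(Metabolite(id=pool, compartment=SHARED))
            t_id = _tag_rxn(f"TU_{base}", tag)
            merged.add_reaction(
                Reaction(
                    id=t_id,
                    stoichiometry={_tag_met(f"{base}[e]", tag): -1.0, pool: 1.0},
                    lower_bound=-1000.0, upper_bound=1000.0, member=tag,
                    name=f"{base} transport to shared pool ({tag})",
                )
            )
            transport_ids[base][tag] = t_id

    exchange_ids = []
    for base in shared_ids:
        pool = f"{base}[{SHARED}]"
        if pool not in merged.metabolites:
            continue
        lo, hi = exchange_bounds.get(base, [-1000.0, 1000.0])
        ex_id = f"EX_{base}[{SHARED}]"
        merged.add_reaction(
            Reaction(
                id=ex_id, stoichiometry={pool: -1.0},
                lower_bound=lo, upper_bound=hi, member=None,
                name=f"{base} community exchange",
            )
        )
        exchange_ids.append(ex_id)

    merged.validate()
    return CommunityModel(
        id=community_id, members=list(members), abundances=abundances,
        merged=merged, shared_ids=shared_ids, exchange_ids=exchange_ids,
        transport_ids=transport_ids,
    )


def abundance_scale(
    S: StoichiometricMatrix,
    abundances: AbundanceVector | dict[str, float],
    exchange_cols: Iterable[str],
    column_members: Mapping[str, str | None],
) -> StoichiometricMatrix:
    """Scale member columns of S by their abundance; exchange columns are the
    identity block and stay untouched.  Every column must be assigned."""
    if isinstance(abundances, dict):
        abundances = AbundanceVector(abundances)
    exchange = set(exchange_cols)
    scale = []
    unassigned = []
    for rid in S.rxn_ids:
        if rid in exchange:
            scale.append(1.0)
            continue
        member = column_members.get(rid)
        if member is None:
            unassigned.append(rid)
            scale.append(1.0)
        else:
            scale.append(abundances[member])
    if unassigned:
        raise CommunityBuildError(
            f"columns not assigned to a member or the exchange block: {unassigned}"
        )
    from scipy import sparse

    scaled = S.matrix @ sparse.diags(scale)
    return StoichiometricMatrix(
        met_ids=list(S.met_ids), rxn_ids=list(S.rxn_ids),
        matrix=sparse.csc_matrix(scaled),
    )


# ---------------------------------------------------------------------------
# coupling and solving
# ---------------------------------------------------------------------------

def add_coupling_constraints(cm, community: CommunityModel, spec: CouplingSpec):
    """Add the three coupling rows to a cobra model built from the *scaled*
    community, plus the auxiliary mu2 variable (member 2 has no biomass
    reaction; mu2 is an accounting variable, not a network column).

    Returns the mu2 solver variable.
    """
    for rxn_id in (spec.growth_id, spec.diff_id, spec.phb_flux_id):
        if rxn_id not in cm.reactions:
            raise CommunityBuildError(
                f"coupling reaction {rxn_id!r} missing from community model"
            )
    x = {rid: community.abundances[community.member_of(rid)]
         for rid in (spec.growth_id, spec.diff_id, spec.phb_flux_id)}
    prob = cm.problem
    growth = cm.reactions.get_by_id(spec.growth_id).flux_expression * x[spec.growth_id]
    diff = cm.reactions.get_by_id(spec.diff_id).flux_expression * x[spec.diff_id]
    phb = cm.reactions.get_by_id(spec.phb_flux_id).flux_expression * x[spec.phb_flux_id]
    mu2 = prob.Variable("mu2_accrual", lb=-1000.0, ub=1000.0)
    rows = [
        prob.Constraint(phb - spec.alpha * diff, lb=0, ub=0, name="phb_topup"),
        prob.Constraint(mu2 - diff - spec.mw_phb / 1000.0 * phb, lb=0, ub=0,
                        name="member2_accrual"),
        prob.Constraint(mu2 - spec.r * growth, lb=0, ub=0, name="fixed_abundance"),
    ]
    cm.add_cons_vars([mu2, *rows])
    return mu2


def solve_xfba(
    community: CommunityModel,
    spec: CouplingSpec | None,
    objective: str | None = None,
    fixed: Mapping[str, float] | None = None,
    parsimonious: bool = True,
    nitrogenase_id: str | None = None,
) -> FluxSolution:
    """Solve XFBA: FBA over S_x with the coupling rows.

    ``objective`` defaults to the growing member's growth reaction.  ``fixed``
    pins are equalities; pins on community exchange reactions are on the
    community basis, pins on member reactions on the member basis.  The
    solution carries per-member aggregates under ``members`` and community
    totals under ``members['community']``.
    """
    cm = to_cobra(community.scaled_model())
    if spec is not None:
        add_coupling_constraints(cm, community, spec)
        if objective is None:
            objective = spec.growth_id
    with cm:
        _apply_pins(cm, fixed)
        sol = _solve(cm, objective, maximize=True, parsimonious=parsimonious)
    if not sol.optimal:
        return sol
    sol.members = _member_summary(community, spec, sol, nitrogenase_id)
    return sol


def _member_summary(
    community: CommunityModel,
    spec: CouplingSpec | None,
    sol: FluxSolution,
    nitrogenase_id: str | None,
) -> dict[str, dict[str, float]]:
    agg = community.aggregate
    out: dict[str, dict[str, float]] = {tag: {} for tag, _ in community.members}
    totals: dict[str, float] = {}
    if spec is not None:
        mu1 = agg(sol.fluxes, spec.growth_id)
        mu1_star = agg(sol.fluxes, spec.diff_id)
        v_phb = agg(sol.fluxes, spec.phb_flux_id)
        mu2 = mu1_star + spec.mw_phb * v_phb / 1000.0
        m1 = community.member_of(spec.growth_id)
        m2 = community.member_of(spec.phb_flux_id)
        out[m1].update({"mu1": mu1, "mu1_star": mu1_star})
        out[m2].update({"mu2": mu2, "v_phb": v_phb})
        totals["community_growth"] = mu1 + mu2
    if nitrogenase_id is not None and nitrogenase_id in sol.fluxes:
        m = community.member_of(nitrogenase_id)
        out[m]["n2_fixation"] = agg(sol.fluxes, nitrogenase_id)
    # per-member share of each shared species (positive = into the pool)
    for base, per_member in community.transport_ids.items():
        for tag, t_id in per_member.items():
            out[tag][f"export_{base}"] = agg(sol.fluxes, t_id)
    sol_members = {**out, "community": totals}
    return sol_members


def member_phb_content(
    solution: FluxSolution, spec: CouplingSpec, community: CommunityModel
) -> dict[str, float | None]:
    """PHB mass fraction per member implied by a coupled optimal solution.

    The growing member keeps the base biomass fraction; the non-growing member
    carries ``(p_base*mu1_star + MW_PHB*v_PHB/1000) / mu2`` — base PHB arriving
    with differentiated cells plus the top-up flux, per gram of accrued
    biomass.  Undefined (None) when mu2 = 0.
    """
    agg = community.aggregate
    mu1_star = agg(solution.fluxes, spec.diff_id)
    v_phb = agg(solution.fluxes, spec.phb_flux_id)
    mu2 = mu1_star + spec.mw_phb * v_phb / 1000.0
    m1 = community.member_of(spec.growth_id)
    m2 = community.member_of(spec.phb_flux_id)
    if abs(mu2) < FEASIBILITY_TOL:
        return {m1: spec.p_base, m2: None}
    content2 = (spec.p_base * mu1_star + spec.mw_phb * v_phb / 1000.0) / mu2
    return {m1: spec.p_base, m2: content2}
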