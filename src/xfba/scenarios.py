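"""The computational-experiment battery.

Every scenario takes models or communities built elsewhere, runs a grid of
LP solves, and returns a :class:`~xfba.fba.ScenarioResult` (or
:class:`PCAResult`) whose summaries are recomputable from the stored flux
solutions.  Infeasible grid points are recorded, never skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .community import (
    AbundanceVector,
    CommunityModel,
    CouplingSpec,
    add_coupling_constraints,
    build_community,
    differentiation_coefficient,
    member_phb_content,
    solve_xfba,
)
from .fba import (
    FluxSolution,
    ScenarioResult,
    min_exchange_for_feasibility,
    secretion_magnitude,
    solve_fba,
    uptake_magnitude,
)
from .model import MetabolicModel
from .network import carbon_matched_uptake

__all__ = [
    "CarbonSource",
    "NitrogenSource",
    "PCAResult",
    "nitrogen_carbon_screen",
    "exchange_robustness",
    "abundance_sensitivity",
    "oxygen_cytochrome_scan",
    "summed_member_fluxes",
    "pca_flux_comparison",
]


@dataclass
class CarbonSource:
    name: str
    exchange_id: str
    carbons: int


@dataclass
class NitrogenSource:
    name: str
    exchange_id: str


def nitrogen_carbon_screen(
    model: MetabolicModel,
    pairs: Sequence[tuple[CarbonSource, NitrogenSource | None]],
    c_reference: tuple[float, int],
    co2_exchange_id: str = "EX_co2",
    nh3_exchange_id: str = "EX_nh3",
    objective: str | None = None,
) -> ScenarioResult:
    """Growth screen over (C source, N source) pairs at carbon-matched uptake.

    For each pair, every listed source exchange is closed, the C source is
    pinned at the rate supplying the reference C-atom flux (uptake as a
    negative equality), and the N source (if distinct) is opened for free
    uptake.  A pair with ``None`` as N source uses the C source for both (the
    glutamine case); its NH3 exchange stays free in both directions so excess
    ammonia can be excreted.  Records growth, N uptake, CO2 release and NH3
    release.
    """
    ref_rate, ref_carbons = c_reference
    all_exchanges = {c.exchange_id for c, _ in pairs} | {
        n.exchange_id for _, n in pairs if n is not None
    }
    grid, solutions, summaries = [], [], []
    for c_src, n_src in pairs:
        unknown = [x for x in (c_src.exchange_id,
                               *( [n_src.exchange_id] if n_src else [] ))
                   if x not in model.reactions]
        if unknown:
            raise KeyError(f"unknown source exchange id(s) {unknown}")
        rate = carbon_matched_uptake(ref_rate, ref_carbons, c_src.carbons)
        scenario = model.copy()
        for ex in all_exchanges:
            if ex in scenario.reactions:
                scenario.reactions[ex].lower_bound = 0.0
        # NH3 free in both directions for the combined C&N source case;
        # otherwise closed to uptake unless NH3 *is* the N source
        if nh3_exchange_id in scenario.reactions:
            scenario.reactions[nh3_exchange_id].lower_bound = 0.0
        n_ex = n_src.exchange_id if n_src is not None else None
        if n_ex is not None:
            scenario.reactions[n_ex].lower_bound = -1000.0
        elif nh3_exchange_id in scenario.reactions:
            scenario.reactions[nh3_exchange_id].lower_bound = -1000.0
        sol = solve_fba(scenario, objective=objective,
                        fixed={c_src.exchange_id: -rate})
        n_label = n_src.name if n_src is not None else c_src.name
        grid.append({"c_source": c_src.name, "n_source": n_label,
                     "c_uptake": rate})
        solutions.append(sol)
        summary: dict = {"status": sol.status, "mu": None, "n_uptake": None,
                         "co2_release": None, "nh3_release": None}
        if sol.optimal:
            summary["mu"] = sol.objective_value
            summary["n_uptake"] = (
                uptake_magnitude(sol, n_ex) if n_ex is not None
                else uptake_magnitude(sol, c_src.exchange_id)
            )
            summary["co2_release"] = secretion_magnitude(sol, co2_exchange_id)
            if nh3_exchange_id in (scenario.reactions):
                summary["nh3_release"] = secretion_magnitude(sol, nh3_exchange_id)
        grid[-1]["n_exchange"] = n_ex or c_src.exchange_id
        summaries.append(summary)
    return ScenarioResult(name="nitrogen_carbon_screen", grid=grid,
                          solutions=solutions, summaries=summaries)


def _community_summary(
    community: CommunityModel, spec: CouplingSpec, sol: FluxSolution,
    nitrogenase_id: str | None,
) -> dict:
    summary: dict = {"status": sol.status}
    if not sol.optimal:
        return summary
    members = sol.members
    summary["community_growth"] = members["community"].get("community_growth")
    for tag, vals in members.items():
        if tag == "community":
            continue
        for key, v in vals.items():
            summary[f"{tag}.{key}"] = v
    return summary


def exchange_robustness(
    community: CommunityModel,
    spec: CouplingSpec,
    metabolite: str,
    flux_grid: Iterable[float],
    fixed: Mapping[str, float] | None = None,
    nitrogenase_id: str | None = None,
) -> ScenarioResult:
    """Pin the inter-member exchange of one shared metabolite across a grid
    spanning both directions and re-solve XFBA at each value.

    The pinned quantity is the community-basis flux of the metabolite from
    the *non-growing* member into the shared pool; negative values mean net
    transfer from the non-growing to the growing member is reversed (the
    growing member feeds the non-growing one).  Sign convention of the grid:
    negative = non-growing -> growing, positive = growing -> non-growing.
    """
    per_member = community.transport_ids.get(metabolite)
    if not per_member:
        raise KeyError(f"{metabolite!r} is not exchangeable between members")
    tag2 = community.member_of(spec.phb_flux_id)
    t2 = per_member[tag2]
    x2 = community.abundances[tag2]
    grid, solutions, summaries = [], [], []
    for value in flux_grid:
        pins = dict(fixed or {})
        # transport is written member -> pool, so non-growing -> growing is a
        # positive transport flux; the grid's sign convention flips it
        pins[t2] = -value / x2
        sol = solve_xfba(community, spec, fixed=pins,
                         nitrogenase_id=nitrogenase_id)
        grid.append({f"exchange_{metabolite}": value})
        solutions.append(sol)
        summaries.append(_community_summary(community, spec, sol, nitrogenase_id))
    return ScenarioResult(
        name=f"exchange_robustness:{metabolite}", grid=grid,
        solutions=solutions, summaries=summaries,
    )


def abundance_sensitivity(
    members: Sequence[tuple[str, MetabolicModel]],
    coupling_template: CouplingSpec,
    nongrowing_fractions: Iterable[float],
    fixed: Mapping[str, float] | None = None,
    shared: Iterable[str] | str = "all-extracellular",
    nitrogenase_id: str | None = None,
    community_setup=None,
) -> ScenarioResult:
    """Rebuild the community at each non-growing fraction f, recompute
    r = f/(1-f) and the differentiation coefficient, and re-solve XFBA.

    ``members`` is [(growing tag, model), (non-growing tag, model)];
    ``community_setup`` is an optional callable applied to each rebuilt
    community (e.g. to close boundary exchanges) before solving.
    """
    (tag1, _), (tag2, _) = members
    grid, solutions, summaries = [], [], []
    for f in nongrowing_fractions:
        if not 0.0 < f < 1.0:
            raise ValueError(f"fraction {f} outside (0, 1)")
        community = build_community(
            members, AbundanceVector({tag1: 1.0 - f, tag2: f}), shared=shared,
        )
        if community_setup is not None:
            community_setup(community)
        spec = CouplingSpec(
            r=f / (1.0 - f), alpha=coupling_template.alpha,
            mw_phb=coupling_template.mw_phb, p_base=coupling_template.p_base,
            growth_id=coupling_template.growth_id,
            diff_id=coupling_template.diff_id,
            phb_flux_id=coupling_template.phb_flux_id,
        )
        sol = solve_xfba(community, spec, fixed=fixed,
                         nitrogenase_id=nitrogenase_id)
        grid.append({"nongrowing_fraction": f, "r": spec.r,
                     "c": differentiation_coefficient(spec)})
        solutions.append(sol)
        summary = _community_summary(community, spec, sol, nitrogenase_id)
        if sol.optimal:
            content = member_phb_content(sol, spec, community)
            summary["phb_content_nongrowing"] = content[tag2]
        solutions[-1] = sol
        summaries.append(summary)
    return ScenarioResult(name="abundance_sensitivity", grid=grid,
                          solutions=solutions, summaries=summaries)


def oxygen_cytochrome_scan(
    community: CommunityModel,
    spec: CouplingSpec,
    o2_grid: Iterable[float],
    o2_exchange_id: str,
    cytc_ids: Mapping[str, str],
    cytbd_ids: Mapping[str, str],
    fixed: Mapping[str, float] | None = None,
    nitrogenase_id: str | None = None,
    refine_threshold: bool = True,
    activation_tol: float = 1e-6,
) -> ScenarioResult:
    """Pin total community O2 uptake across a grid and re-solve XFBA.

    Records community growth and the flux through each member's cytochrome c
    and cytochrome bd oxidases (community basis).  Extras carry the
    feasibility threshold (LP minimization + bisection to 0.01), the
    growth-maximizing O2 value, and the cytochrome-bd activation window of
    the N-fixing member.
    """
    o2_grid = list(o2_grid)
    grid, solutions, summaries = [], [], []
    for o2 in o2_grid:
        pins = dict(fixed or {})
        pins[o2_exchange_id] = -o2
        sol = solve_xfba(community, spec, fixed=pins,
                         nitrogenase_id=nitrogenase_id)
        grid.append({"o2_uptake": o2})
        solutions.append(sol)
        summary = _community_summary(community, spec, sol, nitrogenase_id)
        if sol.optimal:
            for tag in cytc_ids:
                summary[f"{tag}.cytc"] = community.aggregate(
                    sol.fluxes, cytc_ids[tag])
                summary[f"{tag}.cytbd"] = community.aggregate(
                    sol.fluxes, cytbd_ids[tag])
        summaries.append(summary)

    extras: dict[str, object] = {}
    if refine_threshold:
        scaled = community.scaled_model()
        from .fba import to_cobra

        cm = to_cobra(scaled)
        add_coupling_constraints(cm, community, spec)
        cm.objective = spec.growth_id
        try:
            extras["feasibility_threshold"] = min_exchange_for_feasibility(
                cm, o2_exchange_id, fixed=fixed, resolution=0.01,
            )
        except Exception as exc:  # infeasible everywhere: report, don't raise
            extras["feasibility_threshold"] = None
            extras["feasibility_status"] = str(exc)

    feasible = [
        (o2, s.get("community_growth"))
        for o2, s in zip(o2_grid, summaries)
        if s.get("community_growth") is not None
    ]
    if feasible:
        extras["optimal_o2"] = max(feasible, key=lambda t: t[1])[0]
        extras["max_growth"] = max(v for _, v in feasible)
    # which member scavenges the excess O2 can be degenerate, so the
    # activation window is reported on the community level (summed members)
    def total(s, key):
        return sum(s.get(f"{tag}.{key}") or 0.0 for tag in cytbd_ids)

    bd_on = [o2 for o2, s in zip(o2_grid, summaries)
             if s.get("status") == "optimal" and total(s, "cytbd") > activation_tol]
    c_on = [o2 for o2, s in zip(o2_grid, summaries)
            if s.get("status") == "optimal" and total(s, "cytc") > activation_tol]
    extras["bd_activation_onset"] = min(bd_on) if bd_on else None
    extras["cytc_shutoff"] = max(c_on) if c_on else None
    return ScenarioResult(name="oxygen_cytochrome_scan", grid=grid,
                          solutions=solutions, summaries=summaries,
                          extras=extras)


def summed_member_fluxes(
    solution: FluxSolution,
    community: CommunityModel,
    reference_ids: Sequence[str],
) -> np.ndarray:
    """Collapse a community solution onto the single-cell reaction index.

    Member reactions are summed over members on the community basis
    (abundance-weighted); community exchanges map onto the single model's
    exchange of the same base id.  Community plumbing (inter-member
    transports) has no single-cell counterpart and is dropped.  Raises on
    exchange-block reactions that map nowhere.
    """
    index = {rid: i for i, rid in enumerate(reference_ids)}
    transport_set = {
        t for per in community.transport_ids.values() for t in per.values()
    }
    out = np.zeros(len(reference_ids))
    unmapped: list[str] = []
    for rid, rxn in community.merged.reactions.items():
        if rid in transport_set:
            continue
        if rxn.member is not None:
            base = rid[: -len(f"[{rxn.member}]")]
        elif rid.endswith("[u]"):
            base = rid[:-3]
        else:
            base = rid
        if base not in index:
            if rxn.member is None:
                unmapped.append(rid)
            continue
        out[index[base]] += community.aggregate(solution.fluxes, rid)
    if unmapped:
        raise KeyError(
            f"community reactions with no single-model counterpart: {unmapped}"
        )
    return out


@dataclass
class PCAResult:
    """Mean-centred PCA of flux vectors over a common reaction index."""

    explained_variance: np.ndarray  # fractions, sum to 1 (or empty if degenerate)
    scores: np.ndarray  # observations x components
    loadings: np.ndarray  # components x reactions
    mean: np.ndarray
    observation_names: list[str]
    preprocessing: str = "mean-centering only (no unit-variance scaling)"
    degenerate: bool = False

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings + self.mean


def pca_flux_comparison(
    vectors: Mapping[str, Sequence[float]] | np.ndarray,
    observation_names: Sequence[str] | None = None,
) -> PCAResult:
    """PCA across >= 2 flux distributions of equal length.

    Mean-centering only: flux units are homogeneous, so unit-variance scaling
    would distort pathway dominance.  With k observations at most k-1
    components carry variance.  Identical observations give zero total
    variance, reported as degenerate with explained fractions undefined.
    """
    if isinstance(vectors, Mapping):
        observation_names = list(vectors)
        X = np.asarray([np.asarray(v, dtype=float) for v in vectors.values()])
    else:
        X = np.asarray(vectors, dtype=float)
        observation_names = list(observation_names or
                                 [f"obs{i}" for i in range(len(X))])
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 flux vectors of equal length")
    mean = X.mean(axis=0)
    centred = X - mean
    total_var = float((centred ** 2).sum())
    if total_var < 1e-12:
        k = X.shape[0] - 1
        return PCAResult(
            explained_variance=np.array([]),
            scores=np.zeros((X.shape[0], k)),
            loadings=np.zeros((k, X.shape[1])), mean=mean,
            observation_names=observation_names, degenerate=True,
        )
    from sklearn.decomposition import PCA

    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(
        explained_variance=pca.explained_variance_ratio_,
        scores=scores, loadings=pca.components_, mean=pca.mean_,
        observation_names=observation_names,
    )
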