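"""Shared fixtures and the independent dense-LP oracle.

The oracle assembles the abundance-scaled community linear program as a dense
numpy matrix directly from the merged network description and solves it with
scipy's HiGHS backend — a code path and solver disjoint from the package's
cobrapy/GLPK route.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

from xfba import (
    CommunityModel,
    CouplingSpec,
    MetabolicModel,
    Reaction,
    ToySpec,
    make_toy_cell,
    make_toy_community,
)


@pytest.fixture
def toy_spec() -> ToySpec:
    return ToySpec()


@pytest.fixture
def toy_cell(toy_spec) -> MetabolicModel:
    return make_toy_cell(toy_spec)


@pytest.fixture
def toy_community(toy_spec):
    return make_toy_community(toy_spec, nongrowing_fraction=0.1)


@pytest.fixture
def tiny_model() -> MetabolicModel:
    """A <= 12-variable chain with a hand-computable optimum:
    uptake of A (max 5), conversion A -> 2 B, drain of B.  Optimum of EX_b
    is 10 (vertex: EX_a = -5, CONV = 5, EX_b = 10)."""
    m = MetabolicModel(id="tiny")
    m.add_reaction(Reaction("EX_a", {"a[e]": -1.0}, -5.0, 1000.0))
    m.add_reaction(Reaction("T_a", {"a[e]": -1.0, "a[c]": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("CONV", {"a[c]": -1.0, "b[c]": 2.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("T_b", {"b[c]": -1.0, "b[e]": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("EX_b", {"b[e]": -1.0}, 0.0, 1000.0))
    m.objective = "EX_b"
    return m


def dense_lp_optimum(
    model: MetabolicModel,
    objective: str,
    pins: dict[str, float] | None = None,
    maximize: bool = True,
) -> float | None:
    """Plain FBA optimum via a dense linprog model (HiGHS); None if infeasible."""
    rxns = list(model.reactions.values())
    mets = list(model.metabolites)
    mi = {m: i for i, m in enumerate(mets)}
    A = np.zeros((len(mets), len(rxns)))
    for j, r in enumerate(rxns):
        for met, coef in r.stoichiometry.items():
            A[mi[met], j] += coef
    lb = np.array([r.lower_bound for r in rxns])
    ub = np.array([r.upper_bound for r in rxns])
    ids = [r.id for r in rxns]
    for rid, v in (pins or {}).items():
        lb[ids.index(rid)] = ub[ids.index(rid)] = v
    c = np.zeros(len(rxns))
    c[ids.index(objective)] = -1.0 if maximize else 1.0
    res = linprog(c, A_eq=A, b_eq=np.zeros(len(mets)),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        return None
    return -res.fun if maximize else res.fun


def dense_xfba_optimum(
    community: CommunityModel,
    spec: CouplingSpec | None,
    pins: dict[str, float] | None = None,
    objective: str | None = None,
) -> float | None:
    """XFBA optimum via a dense linprog model assembled from first principles:
    member columns scaled by abundance, exchange columns untouched, coupling
    rows appended from the defining identities.  None if infeasible."""
    merged = community.merged
    rxns = list(merged.reactions.values())
    ids = [r.id for r in rxns]
    mets = list(merged.metabolites)
    mi = {m: i for i, m in enumerate(mets)}
    n = len(rxns)
    ncols = n + (1 if spec is not None else 0)  # + mu2 accounting variable
    A = np.zeros((len(mets), ncols))
    for j, r in enumerate(rxns):
        x = community.abundances[r.member] if r.member is not None else 1.0
        for met, coef in r.stoichiometry.items():
            A[mi[met], j] += coef * x
    rows = [A]
    if spec is not None:
        g, d, p = (ids.index(spec.growth_id), ids.index(spec.diff_id),
                   ids.index(spec.phb_flux_id))
        x1 = community.abundances[merged.reactions[spec.growth_id].member]
        x2 = community.abundances[merged.reactions[spec.phb_flux_id].member]
        r1 = np.zeros(ncols); r1[p] = x2; r1[d] = -spec.alpha * x1
        r2 = np.zeros(ncols); r2[-1] = 1.0; r2[d] = -x1
        r2[p] = -spec.mw_phb / 1000.0 * x2
        r3 = np.zeros(ncols); r3[-1] = 1.0; r3[g] = -spec.r * x1
        rows.append(np.vstack([r1, r2, r3]))
    A_eq = np.vstack(rows)
    lb = np.array([r.lower_bound for r in rxns] +
                  ([-1000.0] if spec is not None else []))
    ub = np.array([r.upper_bound for r in rxns] +
                  ([1000.0] if spec is not None else []))
    for rid, v in (pins or {}).items():
        lb[ids.index(rid)] = ub[ids.index(rid)] = v
    c = np.zeros(ncols)
    c[ids.index(objective or spec.growth_id)] = -1.0
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    return -res.fun if res.success else None
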