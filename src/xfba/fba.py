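"""Flux balance analysis on :class:`~xfba.model.MetabolicModel` objects.

The linear programs are built and solved through cobrapy/optlang (GLPK
backend).  All entry points accept the package's own model container and the
conversion to a cobra model happens here, so callers never touch the solver
layer directly.

Sign convention: exchange flux > 0 is secretion; uptake is imposed as a
negative flux (typically a negative lower bound or an equality pin).  Reported
summaries convert uptakes to positive magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import cobra

from .model import MetabolicModel, split_compartment

__all__ = [
    "FluxSolution",
    "FVARange",
    "ScenarioResult",
    "to_cobra",
    "solve_fba",
    "flux_variability",
    "min_exchange_for_feasibility",
    "scan_parameter",
    "InfeasibleProblemError",
]

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-9


class InfeasibleProblemError(RuntimeError):
    """Raised when a problem is infeasible for every admissible setting."""


@dataclass
class FluxSolution:
    """Result of one LP solve."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    members: dict[str, dict[str, float]] = field(default_factory=dict)
    shadow_prices: dict[str, float] | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FVARange:
    reaction_id: str
    minimum: float
    maximum: float
    objective_fraction: float = 1.0

    @property
    def width(self) -> float:
        return self.maximum - self.minimum


@dataclass
class ScenarioResult:
    """Gridded scan output: one solution record per grid point."""

    name: str
    grid: list[dict[str, float]]
    solutions: list[FluxSolution]
    summaries: list[dict[str, float | str | None]]
    extras: dict[str, object] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for point, summary in zip(self.grid, self.summaries):
            rows.append({**point, **summary})
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# conversion
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel) -> cobra.Model:
    """Convert to a cobra model (GLPK solver), preserving ids, bounds and the
    objective."""
    cm = cobra.Model(model.id)
    cm.solver = "glpk"
    mets = {}
    for m in model.metabolites.values():
        met = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        mets[m.id] = met
    reactions = []
    for r in model.reactions.values():
        rxn = cobra.Reaction(r.id, name=r.name)
        rxn.lower_bound = r.lower_bound
        rxn.upper_bound = r.upper_bound
        reactions.append(rxn)
    cm.add_reactions(reactions)
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[k]: v for k, v in r.stoichiometry.items()}
        )
    if model.objective:
        cm.objective = model.objective
    cm.tolerance = FEASIBILITY_TOL
    return cm


def _apply_pins(cm: cobra.Model, fixed: Mapping[str, float] | None) -> None:
    for rxn_id, value in (fixed or {}).items():
        rxn = cm.reactions.get_by_id(rxn_id)
        rxn.bounds = (value, value)


def _solve(
    cm: cobra.Model,
    objective: str | None,
    maximize: bool,
    parsimonious: bool,
) -> FluxSolution:
    if objective is not None:
        cm.objective = objective
    cm.objective_direction = "max" if maximize else "min"
    sol = cm.optimize()
    if sol.status != "optimal":
        return FluxSolution(status=sol.status, objective_value=math.nan)
    objective_value = sol.objective_value
    fluxes = dict(sol.fluxes)
    if parsimonious:
        fluxes = _parsimonize(cm, objective_value) or fluxes
    return FluxSolution(
        status="optimal", objective_value=objective_value, fluxes=fluxes,
        shadow_prices=dict(sol.shadow_prices) if sol.shadow_prices is not None else None,
    )


def _parsimonize(cm: cobra.Model, objective_value: float) -> dict[str, float]:
    """Secondary minimization of total absolute flux at the fixed optimum, so
    reported flux distributions are reproducible despite alternate optima."""
    prob = cm.problem
    with cm:
        pin = prob.Constraint(
            cm.objective.expression,
            lb=objective_value - 1e-9, ub=objective_value + 1e-9,
            name="_pfba_objective_pin",
        )
        cm.add_cons_vars([pin])
        # forward/reverse variables are both non-negative, so their sum is |v|
        total = sum(r.forward_variable + r.reverse_variable for r in cm.reactions)
        cm.objective = prob.Objective(total, direction="min")
        sol = cm.optimize()
        if sol.status != "optimal":  # numerical edge: keep the first solution
            return {}
        return dict(sol.fluxes)


def solve_fba(
    model: MetabolicModel | cobra.Model,
    objective: str | None = None,
    fixed: Mapping[str, float] | None = None,
    maximize: bool = True,
    parsimonious: bool = True,
) -> FluxSolution:
    """Solve max/min c'v subject to S v = 0 and bounds, with optional equality
    pins.  Infeasible and unbounded problems are returned as statuses, never
    raised."""
    cm = to_cobra(model) if isinstance(model, MetabolicModel) else model
    with cm:
        _apply_pins(cm, fixed)
        return _solve(cm, objective, maximize, parsimonious)


def flux_variability(
    model: MetabolicModel | cobra.Model,
    objective_fraction: float = 1.0,
    reactions: Iterable[str] | None = None,
    objective: str | None = None,
    fixed: Mapping[str, float] | None = None,
) -> list[FVARange]:
    """Per-reaction flux ranges at ``objective_fraction`` of the optimum."""
    from cobra.flux_analysis import flux_variability_analysis

    cm = to_cobra(model) if isinstance(model, MetabolicModel) else model
    with cm:
        _apply_pins(cm, fixed)
        if objective is not None:
            cm.objective = objective
        base = cm.slim_optimize(error_value=math.nan)
        if math.isnan(base):
            raise InfeasibleProblemError("base problem is infeasible")
        rxn_list = list(reactions) if reactions is not None else None
        df = flux_variability_analysis(
            cm, reaction_list=rxn_list, fraction_of_optimum=objective_fraction,
            processes=1,
        )
    return [
        FVARange(reaction_id=rid, minimum=row["minimum"], maximum=row["maximum"],
                 objective_fraction=objective_fraction)
        for rid, row in df.iterrows()
    ]


def min_exchange_for_feasibility(
    model: MetabolicModel | cobra.Model,
    exchange_id: str,
    fixed: Mapping[str, float] | None = None,
    resolution: float = 0.01,
    search_bound: float = 1000.0,
) -> float:
    """Minimum pinned uptake magnitude of an exchange at which the problem
    stays feasible.

    The exchange is opened to ``[-search_bound, search_bound]`` and its flux is
    maximized (uptake is negative, so this minimizes the uptake magnitude);
    the boundary is then confirmed by bisection on equality pins to
    ``resolution``.  Raises :class:`InfeasibleProblemError` if no pinned value
    is feasible.
    """
    cm = to_cobra(model) if isinstance(model, MetabolicModel) else model
    with cm:
        _apply_pins(cm, fixed)
        rxn = cm.reactions.get_by_id(exchange_id)
        rxn.bounds = (-search_bound, 0.0)
        sol = _solve(cm, exchange_id, maximize=True, parsimonious=False)
        if not sol.optimal:
            raise InfeasibleProblemError(
                f"no feasible pinned value for {exchange_id}"
            )
        lp_min = -sol.objective_value  # uptake magnitude

    def feasible(uptake: float) -> bool:
        with cm:
            _apply_pins(cm, fixed)
            cm.reactions.get_by_id(exchange_id).bounds = (-uptake, -uptake)
            return not math.isnan(cm.slim_optimize(error_value=math.nan))

    # bisection bracket around the LP boundary, then refine to `resolution`
    lo = max(0.0, lp_min - 1.0)
    hi = lp_min + 1.0
    if feasible(lo):
        return round(lo / resolution) * resolution
    while not feasible(hi):  # pragma: no cover - LP already located boundary
        lo, hi = hi, hi + max(1.0, hi)
        if hi > search_bound:
            raise InfeasibleProblemError(f"no feasible pinned value for {exchange_id}")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return round(hi / resolution) * resolution


def scan_parameter(
    model: MetabolicModel | cobra.Model,
    reaction_id: str,
    values: Iterable[float],
    objective: str | None = None,
    fixed: Mapping[str, float] | None = None,
    parsimonious: bool = False,
    name: str | None = None,
) -> ScenarioResult:
    """Pin one reaction across a grid and re-solve; infeasible points are
    recorded, not skipped."""
    cm = to_cobra(model) if isinstance(model, MetabolicModel) else model
    grid, solutions, summaries = [], [], []
    for value in values:
        pins = dict(fixed or {})
        pins[reaction_id] = value
        sol = solve_fba(cm, objective=objective, fixed=pins,
                        parsimonious=parsimonious)
        grid.append({reaction_id: value})
        solutions.append(sol)
        summaries.append(
            {"status": sol.status,
             "objective": sol.objective_value if sol.optimal else None}
        )
    return ScenarioResult(
        name=name or f"scan:{reaction_id}", grid=grid, solutions=solutions,
        summaries=summaries,
    )


def uptake_magnitude(solution: FluxSolution, exchange_id: str) -> float:
    """Positive uptake magnitude of an exchange flux (0 if secreting)."""
    return max(0.0, -solution.fluxes.get(exchange_id, 0.0))


def secretion_magnitude(solution: FluxSolution, exchange_id: str) -> float:
    return max(0.0, solution.fluxes.get(exchange_id, 0.0))
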