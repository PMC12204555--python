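"""Core data structures for constraint-based metabolic models.

A :class:`MetabolicModel` is a plain container of :class:`Metabolite` and
:class:`Reaction` objects plus an objective reaction id.  Compartments are
encoded as bracketed suffixes on metabolite ids (``succ[c]``, ``succ[e]``,
shared community pool ``succ[u]``); community member copies carry an extra
member tag (``succ[c][m1]``).  Fluxes are in mmol/gDW/h, growth fluxes in 1/h.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FormulaParseError",
    "ModelValidationError",
    "parse_reaction_formula",
    "format_reaction_formula",
    "split_compartment",
    "DEFAULT_BOUND",
]

#: default flux bound magnitude, mmol/gDW/h
DEFAULT_BOUND = 1000.0

_ARROWS_REVERSIBLE = ("<=>", "<->")
_ARROWS_IRREVERSIBLE = ("=>", "->")
_ARROW_RE = re.compile(r"<=>|<->|=>|->")
_COEF_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


class FormulaParseError(ValueError):
    """Raised when a reaction formula string cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a model violates its structural invariants."""


def split_compartment(metabolite_id: str) -> tuple[str, str]:
    """Split a metabolite id into (base, compartment tag).

    The compartment is the last bracketed suffix: ``"succ[e]" -> ("succ", "e")``.
    Ids without a bracketed suffix have compartment ``""``.
    """
    if metabolite_id.endswith("]"):
        i = metabolite_id.rfind("[")
        if i > 0:
            return metabolite_id[:i], metabolite_id[i + 1 : -1]
    return metabolite_id, ""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: dict[str, int] | None = None
    member: str | None = None

    def __post_init__(self) -> None:
        if not self.compartment:
            self.compartment = split_compartment(self.id)[1]
        if self.formula is not None:
            bad = {e: n for e, n in self.formula.items() if n < 0 or n != int(n)}
            if bad:
                raise ModelValidationError(
                    f"metabolite {self.id}: element counts must be non-negative "
                    f"integers, got {bad}"
                )


@dataclass
class Reaction:
    """A stoichiometric reaction; negative coefficients are consumed."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    subsystem: str | None = None
    member: str | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound

    @property
    def is_boundary(self) -> bool:
        """True for reactions touching a single metabolite (system boundary)."""
        return len(self.stoichiometry) == 1

    def is_exchange(self, boundary_compartments: tuple[str, ...] = ("e", "u")) -> bool:
        """Boundary reaction whose single species sits in an outer compartment."""
        if not self.is_boundary:
            return False
        met = next(iter(self.stoichiometry))
        return split_compartment(met)[1] in boundary_compartments

    def formula(self) -> str:
        return format_reaction_formula(self.stoichiometry, self.reversible)

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective: str | None = None

    # -- construction helpers -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, *, create_missing: bool = True) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                if not create_missing:
                    raise ModelValidationError(
                        f"reaction {rxn.id}: unknown metabolite {met_id!r}"
                    )
                self.metabolites[met_id] = Metabolite(id=met_id, member=rxn.member)
        self.reactions[rxn.id] = rxn

    # -- introspection --------------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange()]

    def validate(self) -> None:
        """Check structural invariants, raising ModelValidationError on failure."""
        problems: list[str] = []
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    problems.append(
                        f"reaction {rxn.id} references missing metabolite {met_id}"
                    )
        if self.objective is not None and self.objective not in self.reactions:
            problems.append(f"objective reaction {self.objective!r} not in model")
        if problems:
            raise ModelValidationError("; ".join(problems))

    def copy(self, new_id: str | None = None) -> "MetabolicModel":
        return MetabolicModel(
            id=new_id or self.id,
            metabolites={m.id: replace(m) for m in self.metabolites.values()},
            reactions={r.id: r.copy() for r in self.reactions.values()},
            objective=self.objective,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MetabolicModel({self.id!r}, {self.n_reactions} reactions, "
            f"{self.n_metabolites} metabolites)"
        )


def parse_reaction_formula(text: str) -> tuple[dict[str, float], bool]:
    """Parse a reaction formula string into (stoichiometry, reversible).

    Accepted arrows: ``->``, ``=>`` (irreversible), ``<=>``, ``<->``
    (reversible).  Coefficients default to 1; left-hand species get negative
    coefficients.  Either side may be empty (boundary reactions such as
    ``"succ[e] ->"``).

    >>> parse_reaction_formula("2 qh2 + o2 -> 2 q + 2 h2o")[0]["qh2"]
    -2.0
    """
    arrows = _ARROW_RE.findall(text)
    if len(arrows) != 1:
        raise FormulaParseError(
            f"formula must contain exactly one arrow ('->', '=>', '<->', '<=>'): "
            f"{text!r}"
        )
    arrow = arrows[0]
    lhs, rhs = (side.strip() for side in _ARROW_RE.split(text))
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        if not side:
            return
        for term in re.split(r"\s\+\s|^\+\s|\s\+$", " " + side + " "):
            term = term.strip()
            if not term:
                continue
            parts = term.split(None, 1)
            if len(parts) == 2 and _COEF_RE.match(parts[0]):
                coef, met = float(parts[0]), parts[1].strip()
            else:
                if len(parts) == 2 and re.match(r"^[+-]?[\d.]", parts[0]):
                    raise FormulaParseError(
                        f"non-numeric coefficient {parts[0]!r} in {text!r}"
                    )
                coef, met = 1.0, term
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    if not stoich:
        raise FormulaParseError(f"formula has no species: {text!r}")
    return stoich, arrow in _ARROWS_REVERSIBLE


def _coef_str(c: float) -> str:
    if c == int(c):
        return str(int(c))
    return repr(c)  # shortest string that round-trips the float exactly


def format_reaction_formula(stoich: dict[str, float], reversible: bool) -> str:
    """Serialize stoichiometry to a formula string that re-parses identically."""
    lhs = [(m, -c) for m, c in sorted(stoich.items()) if c < 0]
    rhs = [(m, c) for m, c in sorted(stoich.items()) if c > 0]

    def side(terms: list[tuple[str, float]]) -> str:
        return " + ".join(
            m if c == 1 else f"{_coef_str(c)} {m}" for m, c in terms
        )

    arrow = "<=>" if reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()
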