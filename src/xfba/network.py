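"""Network-level analysis: stoichiometric matrices, dead-end detection, and
biomass-reaction construction from a macromolecular composition.

The biomass builder converts a mass composition (w/w % of macromolecules, each
split into monomers with known molar masses) into stoichiometric coefficients
in mmol per gram dry weight, so that one unit of biomass flux consumes exactly
one gram of monomers.  ``compute_alpha`` gives the extra-PHB coupling
coefficient used when differentiated cells must carry a higher PHB mass
fraction than the cells they derive from, and ``carbon_matched_uptake``
rescales substrate uptake rates so different carbon sources supply the same
C-atom flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import sparse

from .model import MetabolicModel, Reaction

__all__ = [
    "StoichiometricMatrix",
    "BiomassComposition",
    "build_stoichiometric_matrix",
    "find_dead_ends",
    "build_biomass_reaction",
    "compute_alpha",
    "carbon_matched_uptake",
    "default_composition",
]


@dataclass
class StoichiometricMatrix:
    """Sparse stoichiometric matrix with row/column orderings."""

    met_ids: list[str]
    rxn_ids: list[str]
    matrix: sparse.csc_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def column(self, rxn_id: str) -> dict[str, float]:
        """Reconstruct a reaction's stoichiometry from its column."""
        j = self.rxn_ids.index(rxn_id)
        col = self.matrix.getcol(j).tocoo()
        return {self.met_ids[i]: v for i, v in zip(col.row, col.data)}

    def zero_rows(self) -> list[str]:
        mask = np.asarray(abs(self.matrix).sum(axis=1)).ravel() == 0
        return [m for m, z in zip(self.met_ids, mask) if z]

    def zero_columns(self) -> list[str]:
        mask = np.asarray(abs(self.matrix).sum(axis=0)).ravel() == 0
        return [r for r, z in zip(self.rxn_ids, mask) if z]


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions.values()):
        for met, coef in rxn.stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(coef)
    mat = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    return StoichiometricMatrix(met_ids=met_ids, rxn_ids=rxn_ids, matrix=mat)


def find_dead_ends(model: MetabolicModel) -> list[str]:
    """Metabolites that can only be produced or only consumed.

    A reversible reaction (lb < 0 < ub) counts as both a producer and a
    consumer of every species it touches — the case naive scans miss.
    Boundary reactions count too, so a metabolite with an open exchange is
    never a dead end.
    """
    producers: dict[str, bool] = {m: False for m in model.metabolites}
    consumers: dict[str, bool] = {m: False for m in model.metabolites}
    for rxn in model.reactions.values():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met, coef in rxn.stoichiometry.items():
            if coef > 0:
                producers[met] |= fwd
                consumers[met] |= rev
            elif coef < 0:
                consumers[met] |= fwd
                producers[met] |= rev
    return [m for m in model.metabolites if not (producers[m] and consumers[m])]


# ---------------------------------------------------------------------------
# biomass construction
# ---------------------------------------------------------------------------

@dataclass
class BiomassComposition:
    """Macromolecular biomass composition.

    ``macromolecules`` maps name -> mass fraction in w/w % (sums to 100);
    ``monomers`` maps name -> list of (monomer metabolite id, molar mass in
    g/mol, mass fraction within the macromolecule, summing to 1).
    ``ggr`` is an optional growth-associated ATP cost in mmol ATP/gDW.
    """

    macromolecules: dict[str, float]
    monomers: dict[str, list[tuple[str, float, float]]]
    ggr: float | None = None

    def validate(self) -> None:
        total = sum(self.macromolecules.values())
        if abs(total - 100.0) > 0.1:
            raise ValueError(
                f"macromolecule fractions sum to {total:.4f} %, expected 100 "
                f"(residual {total - 100.0:+.4f})"
            )
        for name in self.macromolecules:
            if name not in self.monomers:
                raise ValueError(f"no monomer split given for {name!r}")
            within = sum(f for _, _, f in self.monomers[name])
            if abs(within - 1.0) > 1e-3:
                raise ValueError(
                    f"{name}: within-macromolecule fractions sum to {within:.6f} "
                    f"(residual {within - 1.0:+.6f})"
                )


def build_biomass_reaction(
    comp: BiomassComposition,
    reaction_id: str = "BIOMASS",
    product_id: str | None = "biomass[c]",
    energy_ids: dict[str, float] | None = None,
) -> Reaction:
    """Build a biomass reaction from a macromolecular composition.

    Each monomer gets coefficient ``-1000 * (macro%/100) * within / MW`` in
    mmol/gDW so that the consumed monomer mass sums to exactly 1 g per unit
    flux; the biomass product (if any) has coefficient +1.  ``comp.ggr`` adds
    growth-associated ATP hydrolysis via ``energy_ids`` (coefficients per mmol
    ATP, default ATP+H2O -> ADP+Pi+H in the cytosol).
    """
    comp.validate()
    stoich: dict[str, float] = {}
    for macro, pct in comp.macromolecules.items():
        for monomer_id, mw, within in comp.monomers[macro]:
            if mw <= 0:
                raise ValueError(f"{macro}/{monomer_id}: molar mass must be positive")
            coef = 1000.0 * (pct / 100.0) * within / mw
            stoich[monomer_id] = stoich.get(monomer_id, 0.0) - coef
    if comp.ggr:
        energy = energy_ids or {
            "atp[c]": -1.0, "h2o[c]": -1.0, "adp[c]": 1.0, "pi[c]": 1.0, "h[c]": 1.0,
        }
        for met, per_mmol in energy.items():
            stoich[met] = stoich.get(met, 0.0) + comp.ggr * per_mmol
    if product_id:
        stoich[product_id] = stoich.get(product_id, 0.0) + 1.0
    return Reaction(id=reaction_id, stoichiometry=stoich, lower_bound=0.0)


def biomass_mass_closure(rxn: Reaction, molar_masses: dict[str, float]) -> float:
    """Grams of monomers consumed per unit biomass flux (should be 1.000)."""
    return sum(
        -coef * molar_masses[met] / 1000.0
        for met, coef in rxn.stoichiometry.items()
        if met in molar_masses and coef < 0
    )


def load_composition(path: str | Path) -> BiomassComposition:
    """Load a composition TSV with columns
    (macromolecule, fraction_pct, monomer_id, monomer_mw, within_fraction)."""
    import csv

    macromolecules: dict[str, float] = {}
    monomers: dict[str, list[tuple[str, float, float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            macro = row["macromolecule"]
            macromolecules[macro] = float(row["fraction_pct"])
            monomers.setdefault(macro, []).append(
                (row["monomer_id"], float(row["monomer_mw"]),
                 float(row["within_fraction"]))
            )
    return BiomassComposition(macromolecules=macromolecules, monomers=monomers)


def default_composition() -> BiomassComposition:
    """The shipped rhizobial macromolecular composition (8 macromolecules,
    protein-dominated, 15.9 % PHB).  Monomer splits are synthetic
    single-representative placeholders; the mass fractions are the real ones."""
    with resources.as_file(
        resources.files("xfba.data") / "biomass_composition.tsv"
    ) as p:
        return load_composition(p)


# ---------------------------------------------------------------------------
# coupling coefficient and carbon matching
# ---------------------------------------------------------------------------

def compute_alpha(p_base: float, p_target: float, mw_phb: float = 86.0) -> float:
    """Extra PHB (mmol per gram of differentiated biomass) needed to raise the
    PHB mass fraction from ``p_base`` to ``p_target``.

    Per gram of differentiated biomass carrying fraction p_base, topping up to
    a final fraction p_target requires (p_target - p_base)/p_target extra grams
    of PHB, i.e. ``1000 * (p_target - p_base) / p_target / mw_phb`` mmol.
    """
    if not 0.0 <= p_base < 1.0 or not 0.0 < p_target < 1.0:
        raise ValueError("PHB mass fractions must lie in [0, 1)")
    if p_target <= p_base:
        raise ValueError(
            f"target fraction {p_target} must exceed base fraction {p_base}"
        )
    if mw_phb <= 0:
        raise ValueError("mw_phb must be positive")
    return 1000.0 * (p_target - p_base) / p_target / mw_phb


def carbon_matched_uptake(
    ref_rate: float, ref_carbons: int, target_carbons: int
) -> float:
    """Uptake rate of a target C-source supplying the same C-atom flux as the
    reference source (e.g. succinate at 4.16 mmol/gDW/h, 4 carbons)."""
    if ref_carbons < 1 or target_carbons < 1:
        raise ValueError("carbon counts must be >= 1")
    if ref_rate < 0:
        raise ValueError("reference rate must be non-negative")
    return ref_rate * ref_carbons / target_carbons
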