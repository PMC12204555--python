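"""Reading and writing metabolic models.

Three formats are supported:

* **XLSX** — the tabular dialect used by genome-scale model supplements: one
  sheet of reactions (id, name, formula, lower bound, upper bound, subsystem)
  and one sheet of metabolites (id, name, formula, compartment).  Header names
  are matched case/whitespace-insensitively; unmapped columns are reported via
  a logged warning rather than guessed at.
* **TSV** — a portable two-section text file (``# reactions`` / ``# metabolites``
  tables with a ``# model:`` / ``# objective:`` preamble).
* **JSON** — a direct serialization of the in-memory structures.

``read_model_table(write_model(m, path))`` is the identity on ids,
stoichiometry, bounds and compartments.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    format_reaction_formula,
    parse_reaction_formula,
)

__all__ = ["read_model_table", "write_model", "ModelFormatError"]

log = logging.getLogger(__name__)


class ModelFormatError(ValueError):
    """Raised when a model file is malformed (missing columns, bad sections)."""


# canonical name -> accepted header variants (normalized: lowercase, collapsed
# whitespace/underscores/dashes)
_RXN_COLUMNS = {
    "id": {"id", "rxn", "rxn id", "reaction", "reaction id", "abbreviation"},
    "name": {"name", "reaction name", "description"},
    "formula": {"formula", "equation", "reaction formula", "rxn formula"},
    "lower_bound": {"lower bound", "lb", "lower", "min flux"},
    "upper_bound": {"upper bound", "ub", "upper", "max flux"},
    "subsystem": {"subsystem", "pathway", "system"},
}
_MET_COLUMNS = {
    "id": {"id", "met", "met id", "metabolite", "metabolite id", "abbreviation"},
    "name": {"name", "metabolite name", "full name", "description"},
    "formula": {"formula", "chemical formula", "elemental formula"},
    "compartment": {"compartment", "comp", "location"},
}
_RXN_MANDATORY = ("id", "formula")
_MET_MANDATORY = ("id",)


def _norm_header(h: object) -> str:
    return " ".join(str(h).strip().lower().replace("_", " ").replace("-", " ").split())


def _map_columns(
    headers: list[object], spec: dict[str, set[str]], mandatory: tuple[str, ...],
    context: str,
) -> dict[str, int]:
    mapping: dict[str, int] = {}
    unmapped: list[str] = []
    for i, h in enumerate(headers):
        norm = _norm_header(h)
        for canon, variants in spec.items():
            if norm in variants and canon not in mapping:
                mapping[canon] = i
                break
        else:
            unmapped.append(str(h))
    missing = [c for c in mandatory if c not in mapping]
    if missing:
        raise ModelFormatError(
            f"{context}: missing mandatory column(s) {missing}; headers were "
            f"{[str(h) for h in headers]}"
        )
    if unmapped:
        log.warning("%s: ignoring unmapped column(s) %s", context, unmapped)
    return mapping


def _cell(row: list[object], mapping: dict[str, int], key: str) -> object:
    i = mapping.get(key)
    if i is None or i >= len(row):
        return None
    v = row[i]
    if v is None:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    if isinstance(v, str) and not v.strip():
        return None
    return v


def _parse_elemental(text: object) -> dict[str, int] | None:
    if text is None:
        return None
    import re

    counts: dict[str, int] = {}
    for elem, num in re.findall(r"([A-Z][a-z]?)(\d*)", str(text).strip()):
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    return counts or None


def _build_model(
    model_id: str,
    rxn_rows: list[list[object]],
    rxn_map: dict[str, int],
    met_rows: list[list[object]],
    met_map: dict[str, int],
    objective: str | None,
) -> MetabolicModel:
    if not rxn_rows:
        raise ModelFormatError(f"{model_id}: empty reaction table")
    model = MetabolicModel(id=model_id)
    for row in met_rows:
        mid = _cell(row, met_map, "id")
        if mid is None:
            continue
        mid = str(mid).strip()
        if mid in model.metabolites:
            continue
        comp = _cell(row, met_map, "compartment")
        model.add_metabolite(
            Metabolite(
                id=mid,
                name=str(_cell(row, met_map, "name") or ""),
                compartment=str(comp).strip() if comp is not None else "",
                formula=_parse_elemental(_cell(row, met_map, "formula")),
            )
        )
    duplicates: list[str] = []
    for row in rxn_rows:
        rid = _cell(row, rxn_map, "id")
        if rid is None:
            continue
        rid = str(rid).strip()
        if rid in model.reactions:
            duplicates.append(rid)
            continue
        formula = str(_cell(row, rxn_map, "formula"))
        try:
            stoich, reversible = parse_reaction_formula(formula)
        except Exception as exc:
            raise ModelFormatError(f"reaction {rid}: {exc}") from exc
        lb = _cell(row, rxn_map, "lower_bound")
        ub = _cell(row, rxn_map, "upper_bound")
        if lb is None:
            lb = -DEFAULT_BOUND if reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        sub = _cell(row, rxn_map, "subsystem")
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                name=str(_cell(row, rxn_map, "name") or ""),
                subsystem=str(sub) if sub is not None else None,
            )
        )
    if duplicates:
        raise ModelValidationError(f"duplicate reaction id(s): {sorted(set(duplicates))}")
    model.objective = objective
    model.validate()
    return model


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_model_table(path: str | Path, fmt: str | None = None) -> MetabolicModel:
    """Read a model from XLSX, TSV or JSON, inferring the format from the suffix."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("xlsx", "xls"):
        return _read_xlsx(path)
    if fmt in ("tsv", "tab", "txt"):
        return _read_tsv(path)
    if fmt == "json":
        return _read_json(path)
    raise ModelFormatError(f"unknown model format {fmt!r} for {path}")


def _read_xlsx(path: Path) -> MetabolicModel:
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    rxn_sheet = met_sheet = None
    for name in wb.sheetnames:
        low = name.lower()
        if "reaction" in low or low.startswith("rxn"):
            rxn_sheet = rxn_sheet or name
        elif "metabolite" in low or low.startswith("met"):
            met_sheet = met_sheet or name
    if rxn_sheet is None:
        rxn_sheet = wb.sheetnames[0]
    if met_sheet is None and len(wb.sheetnames) > 1:
        met_sheet = wb.sheetnames[1]

    def rows_of(sheet_name: str) -> list[list[object]]:
        return [list(r) for r in wb[sheet_name].iter_rows(values_only=True)]

    rxn_rows = [r for r in rows_of(rxn_sheet) if any(v is not None for v in r)]
    if not rxn_rows:
        raise ModelFormatError(f"{path}: empty reaction sheet {rxn_sheet!r}")
    rxn_map = _map_columns(rxn_rows[0], _RXN_COLUMNS, _RXN_MANDATORY, f"{path}:{rxn_sheet}")
    met_rows: list[list[object]] = []
    met_map: dict[str, int] = {}
    if met_sheet is not None:
        met_rows = [r for r in rows_of(met_sheet) if any(v is not None for v in r)]
        if met_rows:
            met_map = _map_columns(
                met_rows[0], _MET_COLUMNS, _MET_MANDATORY, f"{path}:{met_sheet}"
            )
            met_rows = met_rows[1:]
    return _build_model(path.stem, rxn_rows[1:], rxn_map, met_rows, met_map, None)


def _read_tsv(path: Path) -> MetabolicModel:
    model_id, objective = path.stem, None
    section = None
    tables: dict[str, list[list[str]]] = {"reactions": [], "metabolites": []}
    for raw in path.read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            tag = line.lstrip("#").strip()
            low = tag.lower()
            if low.startswith("model:"):
                model_id = tag.split(":", 1)[1].strip()
            elif low.startswith("objective:"):
                objective = tag.split(":", 1)[1].strip() or None
            elif low in tables:
                section = low
            continue
        if section is None:
            raise ModelFormatError(
                f"{path}: data before a '# reactions' or '# metabolites' section"
            )
        tables[section].append(line.split("\t"))
    rxn_rows = tables["reactions"]
    if not rxn_rows:
        raise ModelFormatError(f"{path}: empty reaction table")
    rxn_map = _map_columns(rxn_rows[0], _RXN_COLUMNS, _RXN_MANDATORY, str(path))
    met_rows = tables["metabolites"]
    met_map = (
        _map_columns(met_rows[0], _MET_COLUMNS, _MET_MANDATORY, str(path))
        if met_rows
        else {}
    )
    return _build_model(
        model_id, rxn_rows[1:], rxn_map, met_rows[1:] if met_rows else [], met_map,
        objective,
    )


def _read_json(path: Path) -> MetabolicModel:
    data = json.loads(path.read_text())
    for key in ("reactions", "metabolites"):
        if key not in data:
            raise ModelFormatError(f"{path}: missing {key!r} entry")
    if not data["reactions"]:
        raise ModelFormatError(f"{path}: empty reaction table")
    model = MetabolicModel(id=data.get("id", path.stem))
    for m in data["metabolites"]:
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", ""),
                formula=m.get("formula"),
                member=m.get("member"),
            )
        )
    dup = [r["id"] for r in data["reactions"]]
    dups = sorted({x for x in dup if dup.count(x) > 1})
    if dups:
        raise ModelValidationError(f"duplicate reaction id(s): {dups}")
    for r in data["reactions"]:
        model.add_reaction(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                name=r.get("name", ""),
                subsystem=r.get("subsystem"),
                member=r.get("member"),
            )
        )
    model.objective = data.get("objective")
    model.validate()
    return model


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_model(model: MetabolicModel, path: str | Path, fmt: str | None = None) -> Path:
    """Write ``model`` to TSV or JSON; returns the path written."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    model.validate()
    if fmt in ("tsv", "tab", "txt"):
        _write_tsv(model, path)
    elif fmt == "json":
        _write_json(model, path)
    else:
        raise ModelFormatError(f"unknown output format {fmt!r}")
    return path


def _num(x: float) -> str:
    return str(int(x)) if x == int(x) else repr(x)


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    lines = [f"# model: {model.id}"]
    if model.objective:
        lines.append(f"# objective: {model.objective}")
    lines.append("# reactions")
    lines.append("id\tname\tformula\tlower_bound\tupper_bound\tsubsystem")
    for r in model.reactions.values():
        formula = format_reaction_formula(r.stoichiometry, r.reversible)
        lines.append(
            "\t".join(
                [r.id, r.name, formula, _num(r.lower_bound), _num(r.upper_bound),
                 r.subsystem or ""]
            )
        )
    lines.append("# metabolites")
    lines.append("id\tname\tformula\tcompartment")
    for m in model.metabolites.values():
        formula = (
            "".join(f"{e}{n if n != 1 else ''}" for e, n in sorted(m.formula.items()))
            if m.formula
            else ""
        )
        lines.append("\t".join([m.id, m.name, formula, m.compartment]))
    path.write_text("\n".join(lines) + "\n")


def _write_json(model: MetabolicModel, path: Path) -> None:
    data = {
        "id": model.id,
        "objective": model.objective,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "member": m.member,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "member": r.member,
            }
            for r in model.reactions.values()
        ],
    }
    path.write_text(json.dumps(data, indent=1))
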