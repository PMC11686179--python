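"""Readers and writers for the two model dialects.

* ``tabular`` — a directory with two TSV sheets, ``metabolites.tsv``
  (id, name, formula, charge, compartment) and ``reactions.tsv``
  (id, name, equation, lb, ub, subsystem, kind). Equations are written as
  ``1 lcts[c] + 1 h2o[c] -> 1 glc_D[c] + 1 gal[c]``.
* ``sbml`` — SBML Level 3 Version 1 with the FBC v2 package. Bracketed
  compartment suffixes are escaped in SIds with the character-code
  convention (``[`` -> ``__91__``, ``]`` -> ``__93__``).

Both dialects round-trip ids, stoichiometry, bounds, subsystems, kinds,
formulas and charges losslessly.
"""

from __future__ import annotations

import csv
import os
from typing import Dict, List, Tuple, Union

import libsbml

from babybiome.core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    Taxonomy,
)

PathLike = Union[str, "os.PathLike[str]"]


class LoadError(ValueError):
    """File does not conform to the declared dialect."""


# ---------------------------------------------------------------------------
# equation strings
# ---------------------------------------------------------------------------

def format_equation(stoichiometry: Dict[str, float]) -> str:
    """Render a stoichiometry map as ``a A + b B -> c C`` (sorted ids)."""

    def fmt(coeff: float) -> str:
        return f"{coeff:g}"

    subs = sorted((m, -c) for m, c in stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in stoichiometry.items() if c > 0)
    left = " + ".join(f"{fmt(c)} {m}" for m, c in subs)
    right = " + ".join(f"{fmt(c)} {m}" for m, c in prods)
    return f"{left} -> {right}"


def parse_equation(equation: str) -> Dict[str, float]:
    """Parse ``a A + b B -> c C`` (or ``<=>``) into a stoichiometry map."""
    for arrow in ("<=>", "<->", "->"):
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            break
    else:
        raise LoadError(f"equation {equation!r} lacks an arrow")
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            parts = term.strip().split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError as exc:
                    raise LoadError(f"bad coefficient in term {term!r}") from exc
                met = parts[1]
            else:
                raise LoadError(f"cannot parse equation term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(left, -1.0)
    add_side(right, +1.0)
    return {m: c for m, c in stoich.items() if c != 0}


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

MET_COLUMNS = ["id", "name", "formula", "charge", "compartment"]
RXN_COLUMNS = ["id", "name", "equation", "lb", "ub", "subsystem", "kind"]


def _read_tsv(path: str) -> List[Dict[str, str]]:
    with open(path, newline="") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))


def read_metabolites_tsv(path: PathLike) -> List[Metabolite]:
    rows = _read_tsv(str(path))
    mets = []
    for row in rows:
        mets.append(
            Metabolite(
                id=row["id"],
                name=row.get("name", ""),
                formula=row.get("formula", ""),
                charge=int(row["charge"]) if row.get("charge") else 0,
                compartment=row.get("compartment", ""),
            )
        )
    return mets


def read_reactions_tsv(path: PathLike) -> List[Reaction]:
    rows = _read_tsv(str(path))
    rxns = []
    for row in rows:
        rxns.append(
            Reaction(
                id=row["id"],
                name=row.get("name", ""),
                stoichiometry=parse_equation(row["equation"]),
                lower_bound=float(row["lb"]),
                upper_bound=float(row["ub"]),
                subsystem=row.get("subsystem", ""),
                kind=row.get("kind", "internal") or "internal",
            )
        )
    return rxns


def _read_tabular(path: str) -> MetabolicModel:
    met_path = os.path.join(path, "metabolites.tsv")
    rxn_path = os.path.join(path, "reactions.tsv")
    for p in (met_path, rxn_path):
        if not os.path.exists(p):
            raise LoadError(f"missing sheet: {p}")
    mets = read_metabolites_tsv(met_path)
    met_ids = {m.id for m in mets}
    if len(met_ids) != len(mets):
        raise LoadError("duplicate metabolite ids in metabolites.tsv")
    rxns = read_reactions_tsv(rxn_path)
    seen = set()
    biomass_id = None
    for rxn in rxns:
        if rxn.id in seen:
            raise LoadError(f"duplicate reaction id: {rxn.id}")
        seen.add(rxn.id)
        unknown = sorted(set(rxn.stoichiometry) - met_ids)
        if unknown:
            raise LoadError(
                f"reaction {rxn.id!r} references metabolites absent from the "
                f"metabolite sheet: {unknown}"
            )
        if rxn.kind == "biomass" and biomass_id is None:
            biomass_id = rxn.id
    model_id = os.path.basename(os.path.normpath(path))
    taxonomy = Taxonomy()
    meta_path = os.path.join(path, "model.tsv")
    if os.path.exists(meta_path):
        meta = {r["key"]: r["value"] for r in _read_tsv(meta_path)}
        model_id = meta.get("id", model_id)
        taxonomy = Taxonomy(
            species=meta.get("species", ""),
            genus=meta.get("genus", ""),
            phylum=meta.get("phylum", ""),
        )
        if meta.get("biomass_id"):
            biomass_id = meta["biomass_id"]
    try:
        return MetabolicModel(
            model_id, mets, rxns, biomass_id=biomass_id, taxonomy=taxonomy
        )
    except ModelError as exc:
        raise LoadError(str(exc)) from exc


def _write_tabular(model: MetabolicModel, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "metabolites.tsv"), "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(MET_COLUMNS)
        for met in sorted(model.metabolites.values(), key=lambda m: m.id):
            writer.writerow([met.id, met.name, met.formula, met.charge, met.compartment])
    with open(os.path.join(path, "reactions.tsv"), "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(RXN_COLUMNS)
        for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
            writer.writerow(
                [
                    rxn.id,
                    rxn.name,
                    format_equation(dict(rxn.stoichiometry)),
                    f"{rxn.lower_bound:g}",
                    f"{rxn.upper_bound:g}",
                    rxn.subsystem,
                    rxn.kind,
                ]
            )
    with open(os.path.join(path, "model.tsv"), "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["key", "value"])
        writer.writerow(["id", model.id])
        writer.writerow(["species", model.taxonomy.species])
        writer.writerow(["genus", model.taxonomy.genus])
        writer.writerow(["phylum", model.taxonomy.phylum])
        writer.writerow(["biomass_id", model.biomass_id or ""])


# ---------------------------------------------------------------------------
# SBML L3 + FBC
# ---------------------------------------------------------------------------

_SID_ESCAPES = [
    ("[", "__91__"),
    ("]", "__93__"),
    ("(", "__40__"),
    (")", "__41__"),
    ("'", "__39__"),
    ("-", "__45__"),
    (".", "__46__"),
    (" ", "__32__"),
]


def _to_sid(raw: str, prefix: str) -> str:
    sid = raw
    for char, escape in _SID_ESCAPES:
        sid = sid.replace(char, escape)
    return prefix + sid


def _from_sid(sid: str, prefix: str) -> str:
    raw = sid[len(prefix):] if sid.startswith(prefix) else sid
    for char, escape in _SID_ESCAPES:
        raw = raw.replace(escape, char)
    return raw


def _notes(**fields: str) -> str:
    body = "".join(
        f"<p>{key}: {value}</p>" for key, value in fields.items() if value
    )
    return f'<notes><body xmlns="http://www.w3.org/1999/xhtml">{body}</body></notes>'


def _parse_notes(node) -> Dict[str, str]:
    out: Dict[str, str] = {}
    if node is None:
        return out
    text = libsbml.XMLNode.convertXMLNodeToString(node)
    for line in text.split("<p>"):
        if "</p>" not in line or ":" not in line:
            continue
        content = line.split("</p>")[0]
        key, _, value = content.partition(":")
        out[key.strip()] = value.strip()
    return out


def _write_sbml(model: MetabolicModel, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    document = libsbml.SBMLDocument(ns)
    document.setPackageRequired("fbc", False)
    sbml_model = document.createModel()
    sbml_model.setId(_to_sid(model.id, ""))
    sbml_model.setName(model.name)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)
    sbml_model.setNotes(
        _notes(
            SPECIES=model.taxonomy.species,
            GENUS=model.taxonomy.genus,
            PHYLUM=model.taxonomy.phylum,
        )
    )

    compartments = sorted({m.compartment for m in model.metabolites.values()})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in sorted(model.metabolites.values(), key=lambda m: m.id):
        s = sbml_model.createSpecies()
        s.setId(_to_sid(met.id, "M_"))
        s.setName(met.name)
        s.setCompartment(met.compartment)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        splug = s.getPlugin("fbc")
        splug.setCharge(met.charge)
        if met.formula:
            splug.setChemicalFormula(met.formula)

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
        r = sbml_model.createReaction()
        r.setId(_to_sid(rxn.id, "R_"))
        r.setName(rxn.name)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        r.setNotes(_notes(SUBSYSTEM=rxn.subsystem, KIND=rxn.kind))
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(_to_sid(met_id, "M_"))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)

    if model.biomass_id is not None:
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction(_to_sid(model.biomass_id, "R_"))
        flux_obj.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(document, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _read_sbml(path: str) -> MetabolicModel:
    document = libsbml.readSBMLFromFile(str(path))
    if document.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise LoadError(
            f"SBML errors in {path}: "
            + document.getErrorLog().toString()
        )
    sbml_model = document.getModel()
    if sbml_model is None:
        raise LoadError(f"no model element in {path}")
    model_notes = _parse_notes(sbml_model.getNotes())
    taxonomy = Taxonomy(
        species=model_notes.get("SPECIES", ""),
        genus=model_notes.get("GENUS", ""),
        phylum=model_notes.get("PHYLUM", ""),
    )

    mets: List[Metabolite] = []
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        splug = s.getPlugin("fbc")
        mets.append(
            Metabolite(
                id=_from_sid(s.getId(), "M_"),
                name=s.getName(),
                formula=splug.getChemicalFormula() if splug.isSetChemicalFormula() else "",
                charge=splug.getCharge() if splug.isSetCharge() else 0,
            )
        )
    met_ids = {m.id for m in mets}

    rxns: List[Reaction] = []
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            mid = _from_sid(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            mid = _from_sid(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        unknown = sorted(set(stoich) - met_ids)
        if unknown:
            raise LoadError(
                f"reaction {r.getId()!r} references undeclared species {unknown}"
            )
        rplug = r.getPlugin("fbc")
        lb = sbml_model.getParameter(rplug.getLowerFluxBound()).getValue()
        ub = sbml_model.getParameter(rplug.getUpperFluxBound()).getValue()
        notes = _parse_notes(r.getNotes())
        rxns.append(
            Reaction(
                id=_from_sid(r.getId(), "R_"),
                name=r.getName(),
                stoichiometry={m: c for m, c in stoich.items() if c != 0},
                lower_bound=lb,
                upper_bound=ub,
                subsystem=notes.get("SUBSYSTEM", ""),
                kind=notes.get("KIND", "internal"),
            )
        )
    if len({r.id for r in rxns}) != len(rxns):
        raise LoadError(f"duplicate reaction ids in {path}")

    biomass_id = None
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        objective = mplug.getObjective(0)
        if objective.getNumFluxObjectives() > 0:
            biomass_id = _from_sid(
                objective.getFluxObjective(0).getReaction(), "R_"
            )
    try:
        return MetabolicModel(
            _from_sid(sbml_model.getId(), ""),
            mets,
            rxns,
            biomass_id=biomass_id,
            taxonomy=taxonomy,
            name=sbml_model.getName(),
        )
    except ModelError as exc:
        raise LoadError(str(exc)) from exc


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_model(path: PathLike, format: str = "sbml") -> MetabolicModel:
    """Load a model from ``sbml`` (file) or ``tabular`` (directory)."""
    path = str(path)
    if not os.path.exists(path):
        raise LoadError(f"no such path: {path}")
    if format == "sbml":
        return _read_sbml(path)
    if format == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown format {format!r}")


def write_model(model: MetabolicModel, path: PathLike, format: str = "sbml") -> None:
    """Write a model as ``sbml`` (file) or ``tabular`` (directory of sheets)."""
    if format == "sbml":
        _write_sbml(model, str(path))
    elif format == "tabular":
        _write_tabular(model, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
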