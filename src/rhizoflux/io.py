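"""Readers and writers for metabolic models: SBML (L3+FBC, legacy L2) and a
JSON dialect that mirrors the SBML content one-to-one.

The JSON dialect exists for fast, dependency-light fixtures; its schema is
documented in ``docs/json_model_schema.md``.  SBML handling goes through
python-libsbml.  Reaction kinds (exchange / sink / demand / ...) are encoded
as SBO terms on write and recovered from them on read, with a structural
fallback for files produced by other tools.
"""

from __future__ import annotations

import json
import os
import re
from pathlib import Path

import libsbml

from .model import (
    DEFAULT_BOUND,
    Metabolite,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    _And,
    _Gene,
    _Or,
    parse_gpr,
)

JSON_SCHEMA_VERSION = 1

_SBO_BY_KIND = {
    "metabolic": "SBO:0000176",
    "transport": "SBO:0000655",
    "exchange": "SBO:0000627",
    "sink": "SBO:0000632",
    "demand": "SBO:0000628",
    "objective-support": "SBO:0000629",
}
_KIND_BY_SBO = {v: k for k, v in _SBO_BY_KIND.items()}


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed."""


def _infer_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        if format not in ("sbml", "json"):
            raise ValueError(f"unknown model format {format!r}")
        return format
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ValueError(
        f"cannot infer model format from {path!r}; pass format='sbml' or 'json'"
    )


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from SBML or the JSON dialect.

    The returned model satisfies all structural invariants; missing bounds
    default to +/-1000 flux units.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    model = _read_sbml(path) if fmt == "sbml" else _read_json(path)
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path,
                format: str | None = None) -> None:
    """Write a model to SBML (Level 3 + FBC v2) or the JSON dialect."""
    model.validate()
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        _write_sbml(model, path)
    else:
        _write_json(model, path)


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _write_json(model: MetabolicModel, path: str | Path) -> None:
    payload = {
        "schema_version": JSON_SCHEMA_VERSION,
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
                "kind": r.kind,
            }
            for r in model.reactions
        ],
        "genes": model.genes,
        "objective": model.objective,
        "notes": model.notes,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def _read_json(path: str | Path) -> MetabolicModel:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: invalid JSON: {exc}") from exc
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c0"),
                formula=m.get("formula"),
                charge=m.get("charge"),
            )
            for m in payload["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v)
                               for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=r.get("gpr", ""),
                kind=r.get("kind", "metabolic"),
            )
            for r in payload["reactions"]
        ]
        return MetabolicModel(
            id=payload.get("id", "model"),
            metabolites=metabolites,
            reactions=reactions,
            genes=list(payload.get("genes", [])),
            objective={k: float(v)
                       for k, v in payload.get("objective", {}).items()},
            notes=dict(payload.get("notes", {})),
        )
    except (KeyError, TypeError, ModelValidationError) as exc:
        if isinstance(exc, ModelValidationError):
            raise
        raise ModelParseError(f"{path}: malformed model element: {exc}") from exc


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _gpr_to_fbc(node, parent) -> None:
    """Recursively mirror a parsed GPR tree into an FBC association."""
    if isinstance(node, _Gene):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(node.gene)
    elif isinstance(node, _And):
        grp = parent.createAnd()
        for child in node.operands:
            _gpr_to_fbc(child, grp)
    elif isinstance(node, _Or):
        grp = parent.createOr()
        for child in node.operands:
            _gpr_to_fbc(child, grp)


def _fbc_to_gpr(assoc, label_by_id: dict[str, str]) -> str:
    if assoc is None:
        return ""
    if assoc.isGeneProductRef():
        return label_by_id.get(assoc.getGeneProduct(), assoc.getGeneProduct())
    parts = [
        _fbc_to_gpr(assoc.getAssociation(i), label_by_id)
        for i in range(assoc.getNumAssociations())
    ]
    joiner = " and " if assoc.isFbcAnd() else " or "
    return "(" + joiner.join(parts) + ")"


def _write_sbml(model: MetabolicModel, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    for comp_id in sorted({m.compartment for m in model.metabolites}):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name or m.id)
        sp.setCompartment(m.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if m.formula:
            splug.setChemicalFormula(m.formula)
        if m.charge is not None:
            splug.setCharge(int(m.charge))

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId(gene)
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bound_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rxn = sbml_model.createReaction()
        rxn.setId(r.id)
        rxn.setName(r.name or r.id)
        rxn.setReversible(r.lower_bound < 0)
        rxn.setFast(False)
        rxn.setSBOTerm(_SBO_BY_KIND[r.kind])
        for mid, coeff in r.stoichiometry.items():
            if coeff < 0:
                ref = rxn.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = rxn.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(mid)
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        tree = parse_gpr(r.gpr)
        if tree is not None:
            gpa = rplug.createGeneProductAssociation()
            _gpr_to_fbc(tree, gpa)

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, weight in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(weight)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _structural_kind(r: Reaction, model: MetabolicModel) -> str:
    if len(r.stoichiometry) == 1:
        mid = next(iter(r.stoichiometry))
        comp = model.get_metabolite(mid).compartment
        if comp.lower().startswith("e") or r.id.startswith("EX_"):
            return "exchange"
        if r.id.startswith(("SK_", "sink_")) or r.lower_bound < 0:
            return "sink"
        return "demand"
    comps = {model.get_metabolite(m).compartment for m in r.stoichiometry}
    return "transport" if len(comps) > 1 else "metabolic"


def _read_sbml(path: str | Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(
            f"{path}: SBML parse error at line {err.getLine()}: "
            f"{err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: file contains no SBML model element")

    level = doc.getLevel()
    mplug = sbml_model.getPlugin("fbc")

    metabolites = []
    boundary_species = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition() or sp.getId().endswith("_b"):
            boundary_species.add(sp.getId())
            continue
        formula, charge = None, None
        splug = sp.getPlugin("fbc")
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                compartment=sp.getCompartment() or "c0",
                formula=formula,
                charge=charge,
            )
        )

    label_by_id = {}
    genes: list[str] = []
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            label_by_id[gp.getId()] = label
            genes.append(label)

    def parameter_value(pid: str) -> float | None:
        par = sbml_model.getParameter(pid)
        return par.getValue() if par is not None else None

    reactions = []
    objective: dict[str, float] = {}
    gene_set = set(genes)
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            if ref.getSpecies() in boundary_species:
                continue
            stoich[ref.getSpecies()] = (
                stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
            )
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            if ref.getSpecies() in boundary_species:
                continue
            stoich[ref.getSpecies()] = (
                stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
            )

        lb = -DEFAULT_BOUND if rxn.getReversible() else 0.0
        ub = DEFAULT_BOUND
        gpr = ""
        rplug = rxn.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            value = parameter_value(rplug.getLowerFluxBound())
            if value is not None:
                lb = value
        if rplug is not None and rplug.isSetUpperFluxBound():
            value = parameter_value(rplug.getUpperFluxBound())
            if value is not None:
                ub = value
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gpr = _fbc_to_gpr(
                rplug.getGeneProductAssociation().getAssociation(), label_by_id
            )

        kl = rxn.getKineticLaw()
        if kl is not None:  # legacy L2 encoding
            for pid, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                par = kl.getParameter(pid)
                if par is not None:
                    if setter == "lb":
                        lb = par.getValue()
                    else:
                        ub = par.getValue()
            par = kl.getParameter("OBJECTIVE_COEFFICIENT")
            if par is not None and par.getValue() != 0:
                objective[rxn.getId()] = par.getValue()
        if not gpr and rxn.isSetNotes():
            match = re.search(
                r"GENE[ _]ASSOCIATION:\s*([^<\n]*)", rxn.getNotesString()
            )
            if match:
                gpr = match.group(1).strip()

        reactions.append(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                kind="metabolic",  # provisional, fixed below
            )
        )

    if mplug is not None and mplug.getNumObjectives() > 0:
        active = mplug.getActiveObjective() or mplug.getObjective(0)
        sign = -1.0 if active.getType() == "minimize" else 1.0
        for i in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(i)
            objective[fo.getReaction()] = sign * fo.getCoefficient()

    model = MetabolicModel(
        id=sbml_model.getId() or "model",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective=objective,
        notes={"sbml_level": f"L{level}" + ("-fbc" if mplug else "")},
    )
    # assign kinds: prefer SBO terms, fall back to structure
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        sbo = rxn.getSBOTermID()
        r = model.reactions[i]
        r.kind = _KIND_BY_SBO.get(sbo) or _structural_kind(r, model)
        if r.kind in ("exchange", "sink", "demand") and len(r.stoichiometry) != 1:
            r.kind = "metabolic"
    # genes used in GPRs but not declared (legacy files) are appended
    used = set()
    for r in model.reactions:
        used |= r.genes
    for g in sorted(used - gene_set):
        model.genes.append(g)
    return model
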