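"""Model I/O: SBML Level 3 (fbc) and a tabular reaction-list dialect.

The SBML writer emits Level 3 Version 1 with the fbc v2 package (flux bounds
as parameters, an active objective, species formula/charge).  The reader
accepts fbc-style bounds and falls back to legacy kinetic-law
``LOWER_BOUND``/``UPPER_BOUND`` parameters, since published supplementary
models predate fbc adoption.  Curation metadata (confidence score, reaction
kind, subsystem, GPR) travels in SBML notes using the COBRA legacy key:value
convention, so a read/write round trip preserves it.

The TSV dialect is a directory with three files:

``metabolites.tsv``
    columns id, name, formula, charge, compartment
``reactions.tsv``
    columns id, name, equation, lb, ub, gpr, subsystem, confidence, kind
``model.tsv``
    key/value rows: id, objective, compartments (``;``-separated), genes
"""

from __future__ import annotations

import math
import os
import re
from typing import Dict, Optional, Tuple

import libsbml

from .netcore import (
    DEFAULT_BOUND,
    Medium,
    MetabolicModel,
    Metabolite,
    ParseError,
    Reaction,
    format_equation,
    parse_equation,
)

_NOTE_KEYS = ("confidence", "kind", "subsystem")
_SBML_BAD = re.compile(r"[^A-Za-z0-9_]")


def read_model(path: str, dialect: str = "sbml") -> MetabolicModel:
    """Read a model from ``path`` in the named dialect ({sbml, tsv})."""
    if dialect == "sbml":
        return _read_sbml(path)
    if dialect == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path: str, dialect: str = "sbml") -> None:
    """Write ``model`` to ``path`` in the named dialect ({sbml, tsv})."""
    if dialect == "sbml":
        _write_sbml(model, path)
    elif dialect == "tsv":
        _write_tsv(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# -- SBML -------------------------------------------------------------------


def _sid(raw: str) -> str:
    """Make a valid SBML SId (prefix leading digits, replace odd characters)."""
    s = _SBML_BAD.sub("__", raw)
    if s and s[0].isdigit():
        s = "_" + s
    return s


def _unsid(sid: str, prefix: str) -> str:
    s = sid[len(prefix):] if sid.startswith(prefix) else sid
    if s.startswith("_") and len(s) > 1 and s[1].isdigit():
        s = s[1:]
    return s.replace("__", "__")


def _notes_string(pairs: Dict[str, str]) -> str:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items() if v not in ("", None))
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">' + body + "</body>"
    )


def _parse_notes(sbase) -> Dict[str, str]:
    out: Dict[str, str] = {}
    if not sbase.isSetNotes():
        return out
    text = sbase.getNotesString()
    for match in re.finditer(r"<p>\s*([^:<]+):\s*([^<]*)</p>", text):
        out[match.group(1).strip()] = match.group(2).strip()
    return out


def _check(result, message: str) -> None:
    if result is None or (isinstance(result, int) and result != libsbml.LIBSBML_OPERATION_SUCCESS):
        raise RuntimeError(f"libsbml error while {message} (code {result})")


def _write_sbml(model: MetabolicModel, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid(model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    comp_ids: Dict[str, str] = {}
    for comp in sorted(model.compartments or {m.compartment for m in model.metabolites}):
        cid = _sid(comp)
        comp_ids[comp] = cid
        c = sm.createCompartment()
        c.setId(cid)
        c.setName(comp)
        c.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId("M_" + _sid(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(comp_ids[met.compartment])
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        splug.setCharge(int(met.charge))
        if met.formula:
            splug.setChemicalFormula(met.formula)

    for gene in sorted(model.gene_ids):
        gp = sm.getPlugin("fbc").createGeneProduct()
        gp.setId("G_" + _sid(gene))
        gp.setLabel(gene)

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId("R_" + _sid(rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        notes = {
            "confidence": "" if rxn.confidence is None else str(rxn.confidence),
            "kind": rxn.kind,
            "subsystem": rxn.subsystem,
            "GENE_ASSOCIATION": rxn.gpr,
        }
        _check(sr.setNotes(_notes_string(notes)), f"writing notes for {rxn.id}")
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + _sid(met_id))
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(float(rxn.lower_bound)))
        rplug.setUpperFluxBound(bound_param(float(rxn.upper_bound)))

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sid(model.objective_id))
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise RuntimeError(f"failed to write SBML to {path}")


def _legacy_bounds(sr) -> Tuple[Optional[float], Optional[float]]:
    """Bounds from a legacy kineticLaw LOWER_BOUND/UPPER_BOUND, if present."""
    kl = sr.getKineticLaw()
    if kl is None:
        return None, None
    lb = ub = None
    for i in range(kl.getNumParameters()):
        p = kl.getParameter(i)
        if p.getId() == "LOWER_BOUND":
            lb = p.getValue()
        elif p.getId() == "UPPER_BOUND":
            ub = p.getValue()
    return lb, ub


def _read_sbml(path: str) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ParseError(
            f"{path}:{err.getLine()}: {err.getMessage().strip()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ParseError(f"{path}: no model element")
    mplug = sm.getPlugin("fbc")

    comp_names = {}
    for i in range(sm.getNumCompartments()):
        c = sm.getCompartment(i)
        comp_names[c.getId()] = c.getName() or c.getId()

    model = MetabolicModel(
        id=sm.getId() or "model", compartments=set(comp_names.values())
    )

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = ""
        charge = 0
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(
            Metabolite(
                id=_unsid(sp.getId(), "M_"),
                name=sp.getName(),
                formula=formula,
                charge=int(charge),
                compartment=comp_names.get(sp.getCompartment(), sp.getCompartment()),
            )
        )

    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            model.gene_ids.add(gp.getLabel() or _unsid(gp.getId(), "G_"))

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _unsid(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _unsid(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()

        rplug = sr.getPlugin("fbc")
        lb = ub = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound())
        if lb is None and ub is None:
            lb, ub = _legacy_bounds(sr)
        if lb is None:
            lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        notes = _parse_notes(sr)
        confidence = notes.get("confidence")
        model.add_reaction(
            Reaction(
                id=_unsid(sr.getId(), "R_"),
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=notes.get("GENE_ASSOCIATION", ""),
                subsystem=notes.get("subsystem", ""),
                confidence=int(confidence) if confidence else None,
                kind=notes.get("kind", "enzymatic"),
            )
        )

    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_id = _unsid(obj.getFluxObjective(0).getReaction(), "R_")

    model.validate()
    return model


# -- TSV --------------------------------------------------------------------

_MET_COLS = ["id", "name", "formula", "charge", "compartment"]
_RXN_COLS = [
    "id", "name", "equation", "lb", "ub", "gpr", "subsystem", "confidence", "kind",
]


def _write_tsv(model: MetabolicModel, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "metabolites.tsv"), "w") as fh:
        fh.write("\t".join(_MET_COLS) + "\n")
        for met in model.metabolites:
            fh.write(
                "\t".join(
                    [met.id, met.name, met.formula, str(met.charge), met.compartment]
                )
                + "\n"
            )
    with open(os.path.join(path, "reactions.tsv"), "w") as fh:
        fh.write("\t".join(_RXN_COLS) + "\n")
        for rxn in model.reactions:
            fh.write(
                "\t".join(
                    [
                        rxn.id,
                        rxn.name,
                        format_equation(rxn),
                        repr(rxn.lower_bound),
                        repr(rxn.upper_bound),
                        rxn.gpr,
                        rxn.subsystem,
                        "" if rxn.confidence is None else str(rxn.confidence),
                        rxn.kind,
                    ]
                )
                + "\n"
            )
    with open(os.path.join(path, "model.tsv"), "w") as fh:
        fh.write(f"id\t{model.id}\n")
        fh.write(f"objective\t{model.objective_id or ''}\n")
        fh.write(f"compartments\t{';'.join(sorted(model.compartments))}\n")
        fh.write(f"genes\t{';'.join(sorted(model.gene_ids))}\n")


def _read_rows(path: str, expected_cols) -> list:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(expected_cols):
            raise ParseError(f"{path}:1: expected columns {list(expected_cols)}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: wrong field count")
            rows.append((lineno, dict(zip(header, fields))))
    return rows


def _read_tsv(path: str) -> MetabolicModel:
    meta: Dict[str, str] = {}
    with open(os.path.join(path, "model.tsv")) as fh:
        for line in fh:
            if line.strip():
                key, _, value = line.rstrip("\n").partition("\t")
                meta[key] = value
    compartments = set(filter(None, meta.get("compartments", "").split(";")))
    model = MetabolicModel(
        id=meta.get("id", "model"),
        compartments=compartments,
        gene_ids=set(filter(None, meta.get("genes", "").split(";"))),
    )
    met_path = os.path.join(path, "metabolites.tsv")
    for lineno, row in _read_rows(met_path, _MET_COLS):
        if compartments and row["compartment"] not in compartments:
            raise ParseError(
                f"{met_path}:{lineno}: unknown compartment {row['compartment']!r}"
            )
        try:
            charge = int(row["charge"])
        except ValueError as exc:
            raise ParseError(f"{met_path}:{lineno}: bad charge") from exc
        try:
            model.add_metabolite(
                Metabolite(
                    id=row["id"],
                    name=row["name"],
                    formula=row["formula"],
                    charge=charge,
                    compartment=row["compartment"],
                )
            )
        except ValueError as exc:
            raise ParseError(f"{met_path}:{lineno}: {exc}") from exc

    rxn_path = os.path.join(path, "reactions.tsv")
    for lineno, row in _read_rows(rxn_path, _RXN_COLS):
        try:
            lb, ub = float(row["lb"]), float(row["ub"])
        except ValueError as exc:
            raise ParseError(f"{rxn_path}:{lineno}: malformed bounds") from exc
        if not (math.isfinite(lb) or lb == -math.inf) or ub != ub:
            raise ParseError(f"{rxn_path}:{lineno}: malformed bounds")
        stoich = parse_equation(row["equation"], location=f"{rxn_path}:{lineno}")
        try:
            model.add_reaction(
                Reaction(
                    id=row["id"],
                    name=row["name"],
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    gpr=row["gpr"],
                    subsystem=row["subsystem"],
                    confidence=int(row["confidence"]) if row["confidence"] else None,
                    kind=row["kind"] or "enzymatic",
                )
            )
        except ValueError as exc:
            raise ParseError(f"{rxn_path}:{lineno}: {exc}") from exc

    model.objective_id = meta.get("objective") or None
    model.validate()
    return model
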