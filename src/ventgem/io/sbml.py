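"""SBML Level 3 Version 1 + FBC v2 reader/writer (via python-libsbml).

Formulas and charges ride on the FBC species attributes, GPRs on FBC gene
product associations, bounds on shared parameters, the biomass objective on
the FBC active objective. The curation evidence tag travels in reaction
notes (``evidence: <tag>``); a known element-free formula — distinct from an
unknown one — is marked by a species note.
"""

from __future__ import annotations

import re
from typing import Dict, Optional

import libsbml

from ..gpr import And, Gene, GPR, Or
from ..model import (
    Compound,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    format_formula,
    parse_formula,
)

__all__ = ["read_sbml", "write_sbml"]

_NOTE = re.compile(r"<p>\s*([^:<]+):\s*([^<]*)</p>")


def _sanitize(sid: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "_", sid)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def _notes_dict(node) -> Dict[str, str]:
    if node is None or not node.isSetNotes():
        return {}
    text = node.getNotesString()
    return {k.strip(): v.strip() for k, v in _NOTE.findall(text)}


def _set_notes(node, entries: Dict[str, str]) -> None:
    if not entries:
        return
    body = "".join(f"<p>{k}: {v}</p>" for k, v in entries.items())
    node.setNotes(
        f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    )


def _gpr_to_association(gpr: GPR, plugin, parent=None):
    if isinstance(gpr, Gene):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(_sanitize(gpr.id))
    elif isinstance(gpr, And):
        node = parent.createAnd()
        for child in gpr.children:
            _gpr_to_association(child, plugin, node)
    elif isinstance(gpr, Or):
        node = parent.createOr()
        for child in gpr.children:
            _gpr_to_association(child, plugin, node)


def _association_to_gpr(assoc, gene_names: Dict[str, str]) -> GPR:
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gid = assoc.getGeneProduct()
        return Gene(gene_names.get(gid, gid))
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i), gene_names)
        for i in range(assoc.getNumAssociations())
    )
    return And(children) if assoc.isFbcAnd() else Or(children)


def write_sbml(model: MetabolicModel, path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sanitize(model.name) if model.name else "model")
    sbml_model.setName(model.name or "model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)
    _set_notes(sbml_model, model.metadata)

    compartments = sorted({c.compartment for c in model.compounds.values()} or {"c"})
    for comp in compartments:
        sc = sbml_model.createCompartment()
        sc.setId(_sanitize(comp))
        sc.setConstant(True)

    id_map: Dict[str, str] = {}
    for cid in sorted(model.compounds):
        c = model.compounds[cid]
        sp = sbml_model.createSpecies()
        sid = "M_" + _sanitize(cid)
        id_map[cid] = sid
        sp.setId(sid)
        sp.setName(c.name or cid)
        sp.setCompartment(_sanitize(c.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if c.charge is not None:
            splug.setCharge(c.charge)
        if c.formula is not None:
            if c.formula:
                splug.setChemicalFormula(format_formula(c.formula))
            else:
                _set_notes(sp, {"formula_empty": "true"})

    for gid in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sanitize(gid))
        gp.setLabel(gid)

    bound_params: Dict[float, str] = {}

    def param_for(value: float) -> str:
        if value not in bound_params:
            pid = f"bound_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        sr = sbml_model.createReaction()
        sr.setId("R_" + _sanitize(rid))
        sr.setName(r.name or rid)
        sr.setFast(False)
        sr.setReversible(r.lower_bound < 0)
        notes = {}
        if r.evidence:
            notes["evidence"] = r.evidence
        _set_notes(sr, notes)
        for cid, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(id_map[cid])
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(param_for(r.lower_bound))
        rplug.setUpperFluxBound(param_for(r.upper_bound))
        if r.gpr is not None:
            assoc = rplug.createGeneProductAssociation()
            _gpr_to_association(r.gpr, rplug, assoc)

    if model.biomass_reaction_id is not None:
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction("R_" + _sanitize(model.biomass_reaction_id))
        flux_obj.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def read_sbml(path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(
            f"SBML parse error in {path}: {err.getMessage() if err else 'unknown'}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"{path} contains no SBML model")
    mplug = sbml_model.getPlugin("fbc")

    def strip(sid: str, prefix: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    compounds = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        splug = sp.getPlugin("fbc")
        charge: Optional[int] = None
        formula = None
        if splug is not None:
            if splug.isSetCharge():
                charge = splug.getCharge()
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
        if formula is None and _notes_dict(sp).get("formula_empty") == "true":
            formula = {}
        compounds.append(
            Compound(
                id=strip(sp.getId(), "M_"),
                name=sp.getName(),
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment(),
            )
        )

    gene_names: Dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_names[gp.getId()] = gp.getLabel() or gp.getId()

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            cid = strip(ref.getSpecies(), "M_")
            stoich[cid] = stoich.get(cid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            cid = strip(ref.getSpecies(), "M_")
            stoich[cid] = stoich.get(cid, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lower, upper = -1000.0, 1000.0
        gpr: GPR = None
        if rplug is not None:
            lp = sbml_model.getParameter(rplug.getLowerFluxBound() or "")
            up = sbml_model.getParameter(rplug.getUpperFluxBound() or "")
            if lp is not None:
                lower = lp.getValue()
            if up is not None:
                upper = up.getValue()
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr = _association_to_gpr(gpa.getAssociation(), gene_names)
        reactions.append(
            Reaction(
                id=strip(sr.getId(), "R_"),
                name=sr.getName(),
                stoichiometry={c: v for c, v in stoich.items() if v != 0.0},
                lower_bound=lower,
                upper_bound=upper,
                gpr=gpr,
                evidence=_notes_dict(sr).get("evidence") or None,
            )
        )

    biomass = None
    if mplug is not None:
        objective = mplug.getActiveObjective()
        if objective is not None and objective.getNumFluxObjectives() > 0:
            biomass = strip(objective.getFluxObjective(0).getReaction(), "R_")

    return MetabolicModel.from_lists(
        compounds,
        reactions,
        biomass_reaction_id=biomass,
        name=sbml_model.getName() or sbml_model.getId(),
        metadata=_notes_dict(sbml_model),
    )
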