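"""SBML I/O in the legacy COBRA dialect (Level 2 Version 4, via libsbml).

This is the dialect of the pre-FBC era model repositories: flux bounds and
objective coefficients live in kinetic-law parameters (``LOWER_BOUND``,
``UPPER_BOUND``, ``OBJECTIVE_COEFFICIENT``), the gene requirement in a notes
line ``GENE_ASSOCIATION: ...``, the subsystem in ``SUBSYSTEM: ...`` and the
chemical formula in ``FORMULA: ...``.

Species ids embed the compartment as a ``_<compartment>`` suffix, stripped
on read when it matches a declared compartment.  Species flagged
``boundaryCondition="true"`` (or with ids suffixed ``_b``) are external
boundary metabolites: they are dropped from stoichiometry, which is how the
two-sided exchange reactions of some published files become the one-sided
boundary reactions of the object model.  Metabolites with no compartment are
written into a default compartment ``c``.
"""

from __future__ import annotations

import re

import libsbml

from ..core import DEFAULT_BOUND, Metabolite, Model, Reaction
from .common import assemble_model

_NOTE_RE = {
    "gene_association": re.compile(r"GENE[ _]?ASSOCIATION:\s*([^<\n]*)", re.IGNORECASE),
    "subsystem": re.compile(r"SUBSYSTEM:\s*([^<\n]*)", re.IGNORECASE),
    "formula": re.compile(r"FORMULA:\s*([^<\n]*)", re.IGNORECASE),
}

_DEFAULT_COMPARTMENT = "c"
_UNITS_ID = "mmol_per_gDW_per_hr"


class SbmlReadError(ValueError):
    """Unreadable file or invalid SBML."""


def _notes_body(lines: list[str]) -> str:
    ps = "".join(f"<p>{line}</p>" for line in lines)
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{ps}</body>'


def _extract_note(notes: str, key: str) -> str:
    m = _NOTE_RE[key].search(notes)
    return m.group(1).strip() if m else ""


def _check(status: int, what: str) -> None:
    if status != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libsbml error {status} while {what}")


def write_sbml(model: Model, path: str) -> None:
    doc = libsbml.SBMLDocument(2, 4)
    sm = doc.createModel()
    _check(sm.setId(model.id or "model"), "setting model id")
    if model.description:
        sm.setName(model.description)

    unit_def = sm.createUnitDefinition()
    unit_def.setId(_UNITS_ID)
    for kind, exponent, scale in (
        (libsbml.UNIT_KIND_MOLE, 1, -3),
        (libsbml.UNIT_KIND_GRAM, -1, 0),
        (libsbml.UNIT_KIND_SECOND, -1, 0),
    ):
        unit = unit_def.createUnit()
        unit.setKind(kind)
        unit.setExponent(exponent)
        unit.setScale(scale)
        unit.setMultiplier(1.0 if kind != libsbml.UNIT_KIND_SECOND else 1.0 / 3600)

    compartments: list[str] = []
    for met in model.metabolites.values():
        comp = met.compartment or _DEFAULT_COMPARTMENT
        if comp not in compartments:
            compartments.append(comp)
    for comp in compartments:
        record = sm.createCompartment()
        _check(record.setId(comp), f"declaring compartment {comp!r}")
        record.setSize(1.0)

    species_id = {}
    for met in model.metabolites.values():
        comp = met.compartment or _DEFAULT_COMPARTMENT
        sid = f"{met.id}_{comp}"
        species_id[met.id] = sid
        sp = sm.createSpecies()
        _check(sp.setId(sid), f"writing species {sid!r}")
        sp.setCompartment(comp)
        if met.name:
            sp.setName(met.name)
        sp.setBoundaryCondition(False)
        sp.setInitialAmount(0.0)
        if met.charge is not None:
            sp.setCharge(int(met.charge))
        if met.formula:
            _check(sp.setNotes(_notes_body([f"FORMULA: {met.formula}"])), "writing species notes")

    for rxn in model.reactions.values():
        r = sm.createReaction()
        _check(r.setId(rxn.id), f"writing reaction {rxn.id!r}")
        if rxn.name:
            r.setName(rxn.name)
        r.setReversible(rxn.lower_bound < 0)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            _check(ref.setSpecies(species_id[met_id]), f"writing stoichiometry of {rxn.id!r}")
            ref.setStoichiometry(abs(coeff))
        notes = []
        if rxn.gpr_text:
            notes.append(f"GENE_ASSOCIATION: {rxn.gpr_text}")
        if rxn.subsystem:
            notes.append(f"SUBSYSTEM: {rxn.subsystem}")
        if notes:
            _check(r.setNotes(_notes_body(notes)), f"writing notes of {rxn.id!r}")
        kl = r.createKineticLaw()
        kl.setMath(libsbml.parseFormula("FLUX_VALUE"))
        for pid, value in (
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            ("OBJECTIVE_COEFFICIENT", rxn.objective_coefficient),
            ("FLUX_VALUE", 0.0),
        ):
            param = kl.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setUnits(_UNITS_ID)

    if not libsbml.writeSBMLToFile(doc, path):
        raise OSError(f"could not write SBML to {path!r}")


def _split_species_id(sid: str, own_compartment: str, declared: list[str]) -> tuple[str, str]:
    candidates = [own_compartment] + [c for c in declared if c != own_compartment]
    for comp in candidates:
        if comp and sid.endswith(f"_{comp}") and len(sid) > len(comp) + 1:
            return sid[: -(len(comp) + 1)], comp
    return sid, own_compartment


def read_sbml(path: str) -> Model:
    doc = libsbml.readSBML(path)
    errors = [
        doc.getError(i)
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        first = errors[0]
        raise SbmlReadError(
            f"invalid SBML in {path!r}: {first.getMessage().strip()} "
            f"(line {first.getLine()}; {len(errors)} error(s) total)"
        )
    sm = doc.getModel()
    if sm is None:
        raise SbmlReadError(f"no SBML model element in {path!r}")

    declared = [sm.getCompartment(i).getId() for i in range(sm.getNumCompartments())]
    metabolites = []
    met_by_species: dict[str, str] = {}
    boundary_species: set[str] = set()
    seen_met_ids: set[str] = set()
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        sid = sp.getId()
        if sp.getBoundaryCondition() or sid.endswith("_b"):
            boundary_species.add(sid)
            continue
        mid, comp = _split_species_id(sid, sp.getCompartment(), declared)
        if mid in seen_met_ids:
            raise SbmlReadError(f"duplicate metabolite id {mid!r} in {path!r}")
        seen_met_ids.add(mid)
        met_by_species[sid] = mid
        notes = sp.getNotesString() if sp.isSetNotes() else ""
        metabolites.append(
            Metabolite(
                id=mid,
                name=sp.getName(),
                formula=_extract_note(notes, "formula"),
                charge=sp.getCharge() if sp.isSetCharge() else None,
                compartment=comp,
            )
        )

    reactions = []
    seen_rxn_ids: set[str] = set()
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        rid = r.getId()
        if rid in seen_rxn_ids:
            raise SbmlReadError(f"duplicate reaction id {rid!r} in {path!r}")
        seen_rxn_ids.add(rid)
        stoich: dict[str, float] = {}

        def _accumulate(ref, sign: float) -> None:
            sid = ref.getSpecies()
            if sid in boundary_species:
                return
            if sid not in met_by_species:
                raise SbmlReadError(f"reaction {rid!r} references unknown species {sid!r}")
            mid = met_by_species[sid]
            stoich[mid] = stoich.get(mid, 0.0) + sign * ref.getStoichiometry()

        for j in range(r.getNumReactants()):
            _accumulate(r.getReactant(j), -1.0)
        for j in range(r.getNumProducts()):
            _accumulate(r.getProduct(j), +1.0)
        stoich = {mid: v for mid, v in stoich.items() if v != 0.0}
        if not stoich:
            raise SbmlReadError(
                f"reaction {rid!r} has no non-boundary metabolites in {path!r}"
            )

        lower = -DEFAULT_BOUND if r.getReversible() else 0.0
        upper = DEFAULT_BOUND
        objective = 0.0
        kl = r.getKineticLaw()
        if kl is not None:
            for j in range(kl.getNumParameters()):
                param = kl.getParameter(j)
                pid, value = param.getId(), param.getValue()
                if pid == "LOWER_BOUND":
                    lower = value
                elif pid == "UPPER_BOUND":
                    upper = value
                elif pid == "OBJECTIVE_COEFFICIENT":
                    objective = value
        notes = r.getNotesString() if r.isSetNotes() else ""
        reactions.append(
            Reaction(
                id=rid,
                name=r.getName(),
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
                objective_coefficient=objective,
                gpr_text=_extract_note(notes, "gene_association"),
                subsystem=_extract_note(notes, "subsystem"),
            )
        )

    return assemble_model(
        id=sm.getId(),
        description=sm.getName() or "",
        metabolites=metabolites,
        reactions=reactions,
    )
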