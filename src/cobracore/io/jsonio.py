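"""Loss-free JSON serialization of models (the fixture dialect).

Schema (version 1)::

    {
      "id": str, "description": str,
      "metabolites": [{"id", "name", "formula", "charge", "compartment"}],
      "genes":       [{"id", "name", "functional"}],
      "reactions":   [{"id", "name", "stoichiometry": {met_id: coeff},
                       "lower_bound", "upper_bound",
                       "objective_coefficient", "gpr", "subsystem"}],
      "media":       {medium_name: {reaction_id: [lb, ub]}}
    }

``id``, ``stoichiometry``, ``lower_bound`` and ``upper_bound`` are required
per reaction; everything else has a default.  Unknown keys are ignored with
a logged warning; a missing required key raises :class:`JsonSchemaError`
naming its JSON path.
"""

from __future__ import annotations

import json
import logging

from ..core import Gene, Metabolite, Model, Reaction
from .common import assemble_model

logger = logging.getLogger(__name__)

_MET_KEYS = {"id", "name", "formula", "charge", "compartment"}
_GENE_KEYS = {"id", "name", "functional"}
_RXN_KEYS = {
    "id",
    "name",
    "stoichiometry",
    "lower_bound",
    "upper_bound",
    "objective_coefficient",
    "gpr",
    "subsystem",
}
_TOP_KEYS = {"id", "description", "metabolites", "genes", "reactions", "media", "version"}


class JsonSchemaError(ValueError):
    """Schema violation; the message carries the offending JSON path."""


def _require(record: dict, key: str, path: str):
    if key not in record:
        raise JsonSchemaError(f"missing required key {key!r} at {path}")
    return record[key]


def _warn_unknown(record: dict, known: set, path: str) -> None:
    extra = set(record) - known
    if extra:
        logger.warning("ignoring unknown keys %s at %s", sorted(extra), path)


def write_json(model: Model, path: str) -> None:
    doc = {
        "version": 1,
        "id": model.id,
        "description": model.description,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        ],
        "genes": [
            {"id": g.id, "name": g.name, "functional": g.functional}
            for g in model.genes.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "objective_coefficient": r.objective_coefficient,
                "gpr": r.gpr_text,
                "subsystem": r.subsystem,
            }
            for r in model.reactions.values()
        ],
        "media": {
            name: {rid: list(bounds) for rid, bounds in medium.items()}
            for name, medium in model.media.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_json(path: str) -> Model:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise JsonSchemaError("top-level JSON value must be an object at $")
    _warn_unknown(doc, _TOP_KEYS, "$")
    metabolites = []
    for i, rec in enumerate(doc.get("metabolites", [])):
        mpath = f"$.metabolites[{i}]"
        _warn_unknown(rec, _MET_KEYS, mpath)
        charge = rec.get("charge")
        metabolites.append(
            Metabolite(
                id=str(_require(rec, "id", mpath)),
                name=rec.get("name", ""),
                formula=rec.get("formula", ""),
                charge=None if charge is None else int(charge),
                compartment=rec.get("compartment", ""),
            )
        )
    genes = []
    for i, rec in enumerate(doc.get("genes", [])):
        gpath = f"$.genes[{i}]"
        _warn_unknown(rec, _GENE_KEYS, gpath)
        genes.append(
            Gene(
                id=str(_require(rec, "id", gpath)),
                name=rec.get("name", ""),
                functional=bool(rec.get("functional", True)),
            )
        )
    reactions = []
    for i, rec in enumerate(doc.get("reactions", [])):
        rpath = f"$.reactions[{i}]"
        _warn_unknown(rec, _RXN_KEYS, rpath)
        stoich = _require(rec, "stoichiometry", rpath)
        if not isinstance(stoich, dict) or not stoich:
            raise JsonSchemaError(f"stoichiometry must be a non-empty object at {rpath}")
        reactions.append(
            Reaction(
                id=str(_require(rec, "id", rpath)),
                name=rec.get("name", ""),
                stoichiometry={str(k): float(v) for k, v in stoich.items()},
                lower_bound=float(_require(rec, "lower_bound", rpath)),
                upper_bound=float(_require(rec, "upper_bound", rpath)),
                objective_coefficient=float(rec.get("objective_coefficient", 0.0)),
                gpr_text=rec.get("gpr", ""),
                subsystem=rec.get("subsystem", ""),
            )
        )
    media = {}
    for name, entries in (doc.get("media") or {}).items():
        media[name] = {
            str(rid): (float(b[0]), float(b[1])) for rid, b in entries.items()
        }
    return assemble_model(
        id=doc.get("id", ""),
        description=doc.get("description", ""),
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        media=media,
    )
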