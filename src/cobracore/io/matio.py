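"""COBRA Toolbox MATLAB-struct I/O (MAT-file v5 via :mod:`scipy.io`).

The Toolbox stores a model as parallel arrays: ``rxns``/``mets``/``genes``
cell arrays of ids, a sparse stoichiometric matrix ``S`` (|mets| x |rxns|),
bound/objective vectors ``lb``/``ub``/``c``, gene rules ``grRules`` (gene-id
text) and ``rules`` (1-based ``x(i)`` index text), plus optional name /
formula / subsystem annotations.  Compartments are carried inside met ids in
the ``id[compartment]`` convention.  The ``rev`` flag is redundant with the
bounds: it is emitted as ``lb < 0`` on write and ignored on read.
"""

from __future__ import annotations

import re

import numpy as np
from scipy import io as sio
from scipy import sparse

from ..core import Gene, Metabolite, Model, Reaction
from ..gpr import gpr_text_to_rules, rules_to_gpr_text
from .common import assemble_model

MANDATORY_FIELDS = ("rxns", "mets", "S", "lb", "ub", "c", "genes", "grRules")
OPTIONAL_STRING_FIELDS = ("rxnNames", "metNames", "metFormulas", "subSystems")

_MET_COMPARTMENT_RE = re.compile(r"^(?P<id>.*)\[(?P<compartment>[^\[\]]+)\]$")


def _cellstr(values: list[str]) -> np.ndarray:
    arr = np.empty((len(values), 1), dtype=object)
    for i, v in enumerate(values):
        arr[i, 0] = v
    return arr


def _sanitize_varname(name: str) -> str:
    cleaned = re.sub(r"\W", "_", name)
    if not cleaned or not cleaned[0].isalpha():
        cleaned = "model" if not cleaned else f"m_{cleaned}"
    return cleaned[:63]


def write_cobra_struct(model: Model, path: str) -> None:
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    gene_ids = list(model.genes)
    n_met, n_rxn = len(met_ids), len(rxn_ids)
    row = {m: i for i, m in enumerate(met_ids)}
    S = sparse.lil_matrix((n_met, n_rxn))
    lb = np.zeros(n_rxn)
    ub = np.zeros(n_rxn)
    c = np.zeros(n_rxn)
    gr_rules: list[str] = []
    rules: list[str] = []
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        for met_id, coeff in rxn.stoichiometry.items():
            S[row[met_id], j] = coeff
        lb[j], ub[j], c[j] = rxn.lower_bound, rxn.upper_bound, rxn.objective_coefficient
        gr_rules.append(rxn.gpr_text)
        rules.append(gpr_text_to_rules(rxn.gpr_text, gene_ids))
    met_labels = []
    charges = np.full(n_met, np.nan)
    for i, mid in enumerate(met_ids):
        met = model.metabolites[mid]
        met_labels.append(f"{mid}[{met.compartment}]" if met.compartment else mid)
        if met.charge is not None:
            charges[i] = met.charge
    struct = {
        "rxns": _cellstr(rxn_ids),
        "rxnNames": _cellstr([model.reactions[r].name for r in rxn_ids]),
        "mets": _cellstr(met_labels),
        "metNames": _cellstr([model.metabolites[m].name for m in met_ids]),
        "metFormulas": _cellstr([model.metabolites[m].formula for m in met_ids]),
        "metCharges": charges.reshape(-1, 1),
        "S": S.tocsc(),
        "lb": lb.reshape(-1, 1),
        "ub": ub.reshape(-1, 1),
        "c": c.reshape(-1, 1),
        "b": np.zeros((n_met, 1)),
        "rev": (lb < 0).astype(float).reshape(-1, 1),
        "genes": _cellstr(gene_ids),
        "grRules": _cellstr(gr_rules),
        "rules": _cellstr(rules),
        "subSystems": _cellstr([model.reactions[r].subsystem for r in rxn_ids]),
        "description": model.description,
    }
    sio.savemat(path, {_sanitize_varname(model.id): struct}, oned_as="column")


def _as_str_list(value, n: int, field: str) -> list[str]:
    """Normalize a simplified cell array to a list of n strings."""
    if n == 0:
        return []
    if isinstance(value, str):
        items = [value]
    elif isinstance(value, np.ndarray):
        items = [v if isinstance(v, str) else ("" if v is None or np.size(v) == 0 else str(v)) for v in value.ravel()]
    elif isinstance(value, (list, tuple)):
        items = ["" if v is None else (v if isinstance(v, str) else ("" if np.size(v) == 0 else str(v))) for v in value]
    else:
        items = [str(value)]
    if len(items) != n:
        raise ValueError(f"field {field!r} has length {len(items)}, expected {n}")
    return items


def _as_float_vector(value, n: int, field: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float)).ravel()
    if arr.size != n:
        raise ValueError(f"field {field!r} has length {arr.size}, expected {n}")
    return arr


def read_cobra_struct(path: str) -> Model:
    contents = sio.loadmat(path, simplify_cells=True)
    names = [k for k in contents if not k.startswith("__")]
    structs = [n for n in names if isinstance(contents[n], dict)]
    if len(structs) != 1:
        raise ValueError(
            f"expected exactly one model struct in {path!r}, found {structs or names}"
        )
    var_name = structs[0]
    struct = contents[var_name]
    for field in MANDATORY_FIELDS:
        if field not in struct:
            raise ValueError(f"COBRA struct is missing mandatory field {field!r}")
    n_rxn = int(np.size(struct["rxns"])) if not isinstance(struct["rxns"], str) else 1
    n_met = int(np.size(struct["mets"])) if not isinstance(struct["mets"], str) else 1
    rxn_ids = _as_str_list(struct["rxns"], n_rxn, "rxns")
    met_labels = _as_str_list(struct["mets"], n_met, "mets")
    S = struct["S"]
    if sparse.issparse(S):
        S = S.tocsc()
    else:
        S = sparse.csc_matrix(np.atleast_2d(np.asarray(S, dtype=float)))
    if S.shape != (n_met, n_rxn):
        raise ValueError(f"S has shape {S.shape}, expected ({n_met}, {n_rxn})")
    lb = _as_float_vector(struct["lb"], n_rxn, "lb")
    ub = _as_float_vector(struct["ub"], n_rxn, "ub")
    c = _as_float_vector(struct["c"], n_rxn, "c")
    n_gene = int(np.size(struct["genes"])) if not isinstance(struct["genes"], str) else 1
    gene_ids = _as_str_list(struct["genes"], n_gene, "genes")
    gr_rules = _as_str_list(struct["grRules"], n_rxn, "grRules")

    rxn_names = _as_str_list(struct.get("rxnNames", [""] * n_rxn), n_rxn, "rxnNames")
    met_names = _as_str_list(struct.get("metNames", [""] * n_met), n_met, "metNames")
    met_formulas = _as_str_list(struct.get("metFormulas", [""] * n_met), n_met, "metFormulas")
    subsystems = _as_str_list(struct.get("subSystems", [""] * n_rxn), n_rxn, "subSystems")
    charges = None
    if "metCharges" in struct:
        charges = _as_float_vector(struct["metCharges"], n_met, "metCharges")

    metabolites = []
    met_ids = []
    for i, label in enumerate(met_labels):
        m = _MET_COMPARTMENT_RE.match(label)
        if m:
            mid, compartment = m.group("id"), m.group("compartment")
        else:
            mid, compartment = label, ""
        met_ids.append(mid)
        charge = None
        if charges is not None and np.isfinite(charges[i]):
            charge = int(charges[i])
        metabolites.append(
            Metabolite(
                id=mid,
                name=met_names[i],
                formula=met_formulas[i],
                charge=charge,
                compartment=compartment,
            )
        )
    reactions = []
    S_coo = S.tocoo()
    stoich_by_col: dict[int, dict[str, float]] = {j: {} for j in range(n_rxn)}
    for i, j, v in zip(S_coo.row, S_coo.col, S_coo.data):
        if v != 0.0:
            stoich_by_col[int(j)][met_ids[int(i)]] = float(v)
    for j, rid in enumerate(rxn_ids):
        stoich = stoich_by_col[j]
        gpr = gr_rules[j]
        if not gpr and "rules" in struct:
            rules = _as_str_list(struct["rules"], n_rxn, "rules")
            gpr = rules_to_gpr_text(rules[j], gene_ids)
        reactions.append(
            Reaction(
                id=rid,
                name=rxn_names[j],
                stoichiometry=stoich,
                lower_bound=float(lb[j]),
                upper_bound=float(ub[j]),
                objective_coefficient=float(c[j]),
                gpr_text=gpr,
                subsystem=subsystems[j],
            )
        )
    description = struct.get("description", "")
    if not isinstance(description, str):
        description = ""
    return assemble_model(
        id=var_name,
        description=description,
        metabolites=metabolites,
        reactions=reactions,
        genes=[Gene(g) for g in gene_ids],
    )
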