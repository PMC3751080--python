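"""Core object model for genome-scale metabolic networks.

A :class:`Model` is a container of :class:`Reaction`, :class:`Metabolite` and
:class:`Gene` records that are mutually aware: every metabolite knows the
reactions whose stoichiometry mentions it, and every gene knows the reactions
whose GPR rule mentions it.  Stoichiometric coefficients follow the usual
sign convention (negative = consumed, positive = produced); flux bounds are
in mmol·gDW⁻¹·h⁻¹.  A reaction touching exactly one metabolite is a boundary
(exchange) reaction — its bounds encode transfer across the system boundary,
i.e. the growth medium.

Reversibility is encoded purely by ``lower_bound < 0``; there is no separate
stored flag.  Iteration order everywhere is insertion order, which makes all
derived outputs (matrices, reports) deterministic.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import sparse

from .gpr import GprExpression, format_gpr, genes_of, parse_gpr

__all__ = [
    "Metabolite",
    "Gene",
    "Reaction",
    "Model",
    "Medium",
    "ArrayModelView",
    "DuplicateIdError",
    "UnknownIdError",
    "add_reactions",
    "remove_reaction",
    "reactions_of_metabolite",
    "genes_of_reaction",
    "boundary_reactions",
    "to_array_view",
    "copy_model",
    "validate_model",
    "models_equal",
]

#: Default bound magnitude (COBRA convention): irreversible [0, 1000],
#: reversible [-1000, 1000].
DEFAULT_BOUND = 1000.0


class DuplicateIdError(ValueError):
    """An id is already registered in the model."""


class UnknownIdError(KeyError):
    """A referenced id does not exist in the model."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


@dataclass
class Metabolite:
    """A biomolecule: chemical formula, charge, compartment, and the set of
    reactions it participates in (maintained by the owning model)."""

    id: str
    name: str = ""
    formula: str = ""
    charge: Optional[int] = None
    compartment: str = ""
    reaction_ids: set[str] = field(default_factory=set)


@dataclass
class Gene:
    """A gene product referenced by GPR rules; ``functional=False`` marks an
    in-silico knockout."""

    id: str
    name: str = ""
    functional: bool = True
    reaction_ids: set[str] = field(default_factory=set)


class Reaction:
    """A biochemical reaction: stoichiometry, flux bounds, objective weight
    and the Boolean gene requirement (GPR).

    ``stoichiometry`` maps metabolite id to coefficient.  The GPR is stored
    as text plus its parsed tree; setting one keeps the other in sync via
    :meth:`set_gpr`.
    """

    def __init__(
        self,
        id: str,
        stoichiometry: dict[str, float],
        name: str = "",
        lower_bound: float = 0.0,
        upper_bound: float = DEFAULT_BOUND,
        objective_coefficient: float = 0.0,
        gpr_text: str = "",
        subsystem: str = "",
    ):
        self.id = id
        self.name = name
        self.stoichiometry = dict(stoichiometry)
        self.lower_bound = float(lower_bound)
        self.upper_bound = float(upper_bound)
        self.objective_coefficient = float(objective_coefficient)
        self.subsystem = subsystem
        self._gpr: Optional[GprExpression] = None
        self._gpr_text = ""
        self.set_gpr(gpr_text)

    @property
    def gpr(self) -> Optional[GprExpression]:
        return self._gpr

    @property
    def gpr_text(self) -> str:
        return self._gpr_text

    @property
    def gene_ids(self) -> set[str]:
        return genes_of(self._gpr)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_boundary(self) -> bool:
        return len(self.stoichiometry) == 1

    def set_gpr(self, text: str) -> None:
        self._gpr = parse_gpr(text)
        self._gpr_text = format_gpr(self._gpr)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Reaction({self.id}: {self.stoichiometry})"


#: A growth-medium definition: exchange-reaction id -> (lower, upper) bound.
Medium = dict[str, tuple[float, float]]


@dataclass
class ArrayModelView:
    """Matrix view of a model: sparse stoichiometric matrix S
    (|metabolites| x |reactions|) plus bound and objective vectors aligned to
    columns.  Row/column order is the model's insertion order."""

    S: sparse.csr_matrix
    row_index: dict[str, int]
    col_index: dict[str, int]
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.row_index)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.col_index)


class Model:
    """Container of reactions, metabolites and genes with bidirectional
    references, plus optional named growth-media definitions."""

    def __init__(self, id: str = "", description: str = ""):
        self.id = id
        self.description = description
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.genes: dict[str, Gene] = {}
        self.media: dict[str, Medium] = {}

    # -- convenience methods delegating to the module-level operations ------
    def add_reactions(self, reactions, metabolites=None):
        return add_reactions(self, reactions, metabolites)

    def remove_reaction(self, reaction_id, prune_orphans=False):
        return remove_reaction(self, reaction_id, prune_orphans)

    def boundary_reactions(self):
        return boundary_reactions(self)

    def to_array_view(self):
        return to_array_view(self)

    def copy(self):
        return copy_model(self)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Model({self.id!r}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes)"
        )


def add_reactions(
    model: Model,
    reactions: Iterable[Reaction],
    metabolites: Optional[Iterable[Metabolite]] = None,
) -> Model:
    """Register reactions (and any new metabolites/genes) with the model.

    Metabolite ids mentioned by a reaction but absent from the model are
    created as bare records, unless a matching record is supplied in
    ``metabolites``.  All backreferences are updated.  Rejects duplicate
    reaction ids and empty stoichiometries; GPR parse errors propagate.
    """
    supplied = {m.id: m for m in metabolites} if metabolites else {}
    reactions = list(reactions)
    for rxn in reactions:
        if rxn.id in model.reactions:
            raise DuplicateIdError(f"reaction id {rxn.id!r} already in model")
        if not rxn.stoichiometry:
            raise ValueError(f"reaction {rxn.id!r} has empty stoichiometry")
        if rxn.lower_bound > rxn.upper_bound:
            raise ValueError(
                f"reaction {rxn.id!r}: lower_bound {rxn.lower_bound} > "
                f"upper_bound {rxn.upper_bound}"
            )
    seen = set()
    for rxn in reactions:
        if rxn.id in seen:
            raise DuplicateIdError(f"reaction id {rxn.id!r} given twice")
        seen.add(rxn.id)
    for rxn in reactions:
        model.reactions[rxn.id] = rxn
        for met_id in rxn.stoichiometry:
            if met_id not in model.metabolites:
                model.metabolites[met_id] = supplied.get(met_id, Metabolite(met_id))
            model.metabolites[met_id].reaction_ids.add(rxn.id)
        for gene_id in rxn.gene_ids:
            if gene_id not in model.genes:
                model.genes[gene_id] = Gene(gene_id)
            model.genes[gene_id].reaction_ids.add(rxn.id)
    return model


def remove_reaction(model: Model, reaction_id: str, prune_orphans: bool = False) -> Model:
    """Remove a reaction and update backreferences; optionally drop
    metabolites/genes left with no referencing reaction."""
    if reaction_id not in model.reactions:
        raise UnknownIdError(f"unknown reaction id {reaction_id!r}")
    rxn = model.reactions.pop(reaction_id)
    for met_id in rxn.stoichiometry:
        met = model.metabolites[met_id]
        met.reaction_ids.discard(reaction_id)
        if prune_orphans and not met.reaction_ids:
            del model.metabolites[met_id]
    for gene_id in rxn.gene_ids:
        gene = model.genes[gene_id]
        gene.reaction_ids.discard(reaction_id)
        if prune_orphans and not gene.reaction_ids:
            del model.genes[gene_id]
    return model


def reactions_of_metabolite(model: Model, metabolite_id: str) -> set[str]:
    """The reactions whose stoichiometry mentions the metabolite."""
    if metabolite_id not in model.metabolites:
        raise UnknownIdError(f"unknown metabolite id {metabolite_id!r}")
    return set(model.metabolites[metabolite_id].reaction_ids)


def genes_of_reaction(model: Model, reaction_id: str) -> set[str]:
    """The genes in the reaction's GPR (empty for spontaneous reactions)."""
    if reaction_id not in model.reactions:
        raise UnknownIdError(f"unknown reaction id {reaction_id!r}")
    return set(model.reactions[reaction_id].gene_ids)


def boundary_reactions(model: Model) -> set[str]:
    """Reactions whose stoichiometry has exactly one metabolite entry —
    external boundary conditions (exchanges)."""
    return {rid for rid, rxn in model.reactions.items() if len(rxn.stoichiometry) == 1}


def to_array_view(model: Model) -> ArrayModelView:
    """Build the stoichiometric matrix and aligned lb/ub/c vectors.

    Rows/columns follow metabolite/reaction insertion order.
    """
    row_index = {mid: i for i, mid in enumerate(model.metabolites)}
    col_index = {rid: j for j, rid in enumerate(model.reactions)}
    n_met, n_rxn = len(row_index), len(col_index)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lb = np.zeros(n_rxn)
    ub = np.zeros(n_rxn)
    c = np.zeros(n_rxn)
    for rid, rxn in model.reactions.items():
        j = col_index[rid]
        lb[j] = rxn.lower_bound
        ub[j] = rxn.upper_bound
        c[j] = rxn.objective_coefficient
        for met_id, coeff in rxn.stoichiometry.items():
            rows.append(row_index[met_id])
            cols.append(j)
            vals.append(coeff)
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(n_met, n_rxn))
    return ArrayModelView(S=S, row_index=row_index, col_index=col_index, lb=lb, ub=ub, c=c)


def copy_model(model: Model) -> Model:
    """Deep, independent copy preserving insertion order."""
    return _copy.deepcopy(model)


def validate_model(model: Model) -> list[str]:
    """Full invariant sweep; returns a list of violations (empty = valid).

    Checks id-key consistency, bound ordering, non-empty stoichiometry,
    closure of all cross-references, and exact bidirectionality of the
    metabolite<->reaction and gene<->reaction links.
    """
    problems: list[str] = []
    for mid, met in model.metabolites.items():
        if met.id != mid:
            problems.append(f"metabolite key {mid!r} != record id {met.id!r}")
    for gid, gene in model.genes.items():
        if gene.id != gid:
            problems.append(f"gene key {gid!r} != record id {gene.id!r}")
    met_refs: dict[str, set[str]] = {mid: set() for mid in model.metabolites}
    gene_refs: dict[str, set[str]] = {gid: set() for gid in model.genes}
    for rid, rxn in model.reactions.items():
        if rxn.id != rid:
            problems.append(f"reaction key {rid!r} != record id {rxn.id!r}")
        if not rxn.stoichiometry:
            problems.append(f"reaction {rid!r} has empty stoichiometry")
        if rxn.lower_bound > rxn.upper_bound:
            problems.append(f"reaction {rid!r} has lower_bound > upper_bound")
        for met_id in rxn.stoichiometry:
            if met_id not in model.metabolites:
                problems.append(f"reaction {rid!r} references unknown metabolite {met_id!r}")
            else:
                met_refs[met_id].add(rid)
        for gene_id in rxn.gene_ids:
            if gene_id not in model.genes:
                problems.append(f"reaction {rid!r} GPR references unknown gene {gene_id!r}")
            else:
                gene_refs[gene_id].add(rid)
    for mid, expected in met_refs.items():
        if model.metabolites[mid].reaction_ids != expected:
            problems.append(
                f"metabolite {mid!r} reaction_ids {model.metabolites[mid].reaction_ids} "
                f"!= cross-scan {expected}"
            )
    for gid, expected in gene_refs.items():
        if model.genes[gid].reaction_ids != expected:
            problems.append(
                f"gene {gid!r} reaction_ids {model.genes[gid].reaction_ids} "
                f"!= cross-scan {expected}"
            )
    return problems


def models_equal(a: Model, b: Model, check_order: bool = True) -> bool:
    """Structural equality: ids, names, formulas, compartments, charges,
    stoichiometry, bounds, objective coefficients, subsystems and GPR trees.

    GPRs are compared as parsed trees (canonical n-ary form), so logically
    re-parenthesized texts compare equal.  With ``check_order`` the insertion
    order of reactions and metabolites must also match.
    """
    if set(a.reactions) != set(b.reactions) or set(a.metabolites) != set(b.metabolites):
        return False
    if set(a.genes) != set(b.genes):
        return False
    if check_order:
        if list(a.reactions) != list(b.reactions) or list(a.metabolites) != list(b.metabolites):
            return False
    for mid, ma in a.metabolites.items():
        mb = b.metabolites[mid]
        if (ma.name, ma.formula, ma.charge, ma.compartment) != (
            mb.name,
            mb.formula,
            mb.charge,
            mb.compartment,
        ):
            return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        if ra.stoichiometry != rb.stoichiometry:
            return False
        if (ra.lower_bound, ra.upper_bound, ra.objective_coefficient) != (
            rb.lower_bound,
            rb.upper_bound,
            rb.objective_coefficient,
        ):
            return False
        if (ra.name, ra.subsystem) != (rb.name, rb.subsystem):
            return False
        if ra.gpr != rb.gpr:
            return False
    return True
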