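"""Shared assembly helper for the format readers."""

from __future__ import annotations

from typing import Iterable, Optional

from ..core import Gene, Metabolite, Model, Reaction, add_reactions


def assemble_model(
    id: str,
    description: str,
    metabolites: Iterable[Metabolite],
    reactions: Iterable[Reaction],
    genes: Optional[Iterable[Gene]] = None,
    media: Optional[dict] = None,
) -> Model:
    """Build a model preserving the listed metabolite/gene order.

    Metabolite and gene records are registered first (so reaction
    registration links against them instead of creating bare records), then
    reactions; genes named in GPRs but absent from ``genes`` are created on
    the fly.
    """
    model = Model(id=id, description=description)
    for met in metabolites:
        if met.id in model.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        model.metabolites[met.id] = met
    if genes is not None:
        for gene in genes:
            if gene.id in model.genes:
                raise ValueError(f"duplicate gene id {gene.id!r}")
            model.genes[gene.id] = gene
    add_reactions(model, reactions)
    if media:
        model.media = {name: dict(entries) for name, entries in media.items()}
    return model
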