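"""Reporter-metabolite analysis.

Given per-gene significance scores (p-values, e.g. from differential
expression), a reporter metabolite is one whose network neighborhood — the
genes catalyzing the reactions it participates in — is collectively more
significant than chance.  Each gene p-value is converted to a z-score
(z = Phi^-1(1 - p)); a metabolite with k scored neighborhood genes gets the
aggregate

    z_raw = (sum of neighborhood z) / sqrt(k),

which is then corrected against a sampled background: for each occurring k,
``n_background`` random size-k gene sets are drawn (without replacement)
from the scored genes present in the model, and

    z_corrected = (z_raw - mu_k) / sigma_k,
    p_corrected = 1 - Phi(z_corrected).

The correction removes the dependence of the aggregate on neighborhood size
so metabolites with different connectivity are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import Model, UnknownIdError

__all__ = [
    "GeneScoreTable",
    "ReporterEntry",
    "ReporterScores",
    "p_to_z",
    "metabolite_neighborhood",
    "reporter_scores",
    "read_gene_scores",
]

#: gene id -> p-value in (0, 1)
GeneScoreTable = dict

#: p-values are clamped into this open interval before the normal-quantile
#: transform, which diverges at 0 and 1.
P_CLAMP = 1e-15


def p_to_z(p) -> np.ndarray | float:
    """Convert an upper-tail p-value to a z-score: z = Phi^-1(1 - p).

    Small p (strong signal) gives large positive z; p = 0.5 gives z = 0.
    Values are clamped to [1e-15, 1 - 1e-15] first.
    """
    p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    return stats.norm.isf(p)


def metabolite_neighborhood(model: Model, metabolite_id: str) -> set[str]:
    """All genes over all reactions the metabolite participates in."""
    if metabolite_id not in model.metabolites:
        raise UnknownIdError(f"unknown metabolite id {metabolite_id!r}")
    out: set[str] = set()
    for rid in model.metabolites[metabolite_id].reaction_ids:
        out |= model.reactions[rid].gene_ids
    return out


@dataclass
class ReporterEntry:
    metabolite_id: str
    k: int
    z_raw: float
    z_corrected: float
    p_corrected: float


@dataclass
class ReporterScores:
    """Reporter statistics, sorted by ``z_corrected`` descending (ties broken
    by metabolite id).  ``unscored`` lists metabolites whose neighborhood
    contains no scored gene (k = 0)."""

    entries: list[ReporterEntry]
    unscored: list[str]

    def __iter__(self):
        return iter(self.entries)

    def ranked_ids(self) -> list[str]:
        return [e.metabolite_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.metabolite_id, e.k, e.z_raw, e.z_corrected, e.p_corrected)
                for e in self.entries
            ],
            columns=["metabolite_id", "k", "z_raw", "z_corrected", "p_corrected"],
        )


def reporter_scores(
    model: Model,
    scores: GeneScoreTable,
    n_background: int = 1000,
    seed: int = 0,
) -> ReporterScores:
    """Score every metabolite of the model against the gene-score table.

    Neighborhood genes without a score entry are ignored (k counts scored
    genes only).  The background for each occurring neighborhood size k is
    ``n_background`` size-k samples drawn without replacement from the
    scored genes present in the model, with a seeded generator — fixed seed
    and inputs give bit-identical output.
    """
    if not scores:
        raise ValueError("empty gene-score table")
    if n_background < 100:
        raise ValueError("n_background must be >= 100")
    scored_genes = [g for g in model.genes if g in scores]
    if not scored_genes:
        raise ValueError("no gene in the score table is present in the model")
    z_by_gene = {g: float(p_to_z(scores[g])) for g in scored_genes}
    z_pool = np.array([z_by_gene[g] for g in scored_genes])

    neighborhoods: dict[str, list[str]] = {}
    unscored: list[str] = []
    for mid in model.metabolites:
        genes = sorted(g for g in metabolite_neighborhood(model, mid) if g in z_by_gene)
        if genes:
            neighborhoods[mid] = genes
        else:
            unscored.append(mid)

    rng = np.random.default_rng(seed)
    sizes = sorted({len(g) for g in neighborhoods.values()})
    background: dict[int, tuple[float, float]] = {}
    for k in sizes:
        if k > len(z_pool):
            k_eff = len(z_pool)
        else:
            k_eff = k
        samples = np.empty(n_background)
        for b in range(n_background):
            idx = rng.choice(len(z_pool), size=k_eff, replace=False)
            samples[b] = z_pool[idx].sum() / np.sqrt(k_eff)
        background[k] = (float(samples.mean()), float(samples.std()))

    entries: list[ReporterEntry] = []
    for mid, genes in neighborhoods.items():
        k = len(genes)
        z_raw = sum(z_by_gene[g] for g in genes) / np.sqrt(k)
        mu_k, sigma_k = background[k]
        if sigma_k == 0:
            warnings.warn(
                f"degenerate background (sigma=0) at neighborhood size {k}; "
                "z_corrected set to 0",
                stacklevel=2,
            )
            z_corr = 0.0
        else:
            z_corr = (z_raw - mu_k) / sigma_k
        p_corr = float(np.clip(stats.norm.sf(z_corr), P_CLAMP, 1.0 - P_CLAMP))
        entries.append(ReporterEntry(mid, k, float(z_raw), float(z_corr), p_corr))

    entries.sort(key=lambda e: (-e.z_corrected, e.metabolite_id))
    return ReporterScores(entries=entries, unscored=unscored)


def read_gene_scores(path: str) -> GeneScoreTable:
    """Read a two-column TSV (gene_id, p_value; header required)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"gene_id", "p_value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"score table needs columns {sorted(required)}; got {list(frame.columns)}")
    return {str(g): float(p) for g, p in zip(frame["gene_id"], frame["p_value"])}
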