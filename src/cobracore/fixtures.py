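"""Desk-scale fixture models and seeded random-model generators.

These stand in for genome-scale reconstructions so every analysis is
testable in milliseconds with hand-derivable optima.  All stoichiometric
coefficients are +/-1 (one fixture exercises a coefficient-2 step so the
I/O and LP paths see non-unit stoichiometry).

The diamond network::

        EX_A          R1 (g1)      R3 (g3)        EX_D
    0 ----->  A  --+----------> B ---------> D ----------> 0
     [0,10]       |                          ^    (objective)
                  +----------> C ------------+
                     R2 (g2)      R4 (g4)

Source uptake is capped at 10, so the FBA optimum is 10; R1/R2 (and R3/R4)
are parallel branches — each gene individually dispensable, each branch pair
{g1,g2} and {g3,g4} synthetically lethal.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import Gene, Metabolite, Model, Reaction, add_reactions
from .topology import metabolite_neighborhood

__all__ = [
    "make_diamond",
    "make_chain",
    "make_coefficient_chain",
    "random_model",
    "random_scores",
    "load_fixture",
    "FIXTURE_NAMES",
]


def _met(mid: str) -> Metabolite:
    return Metabolite(mid, name=mid, compartment="c")


def make_diamond(convention: str = "source") -> Model:
    """The 6-reaction / 4-metabolite diamond network (optimum 10).

    ``convention="source"`` writes the boundary reactions in production form
    (EX_A: 0 -> A with bounds [0, 10]; EX_D: D -> 0).  ``"exchange"`` writes
    both in the conventional exchange form (met -> 0) where uptake is a
    negative flux: EX_A gets bounds [-10, 1000] and the model carries a
    stored ``minimal`` medium definition for it.
    """
    model = Model(id="diamond", description="diamond toy network")
    mets = [_met(m) for m in "ABCD"]
    if convention == "source":
        ex_a = Reaction("EX_A", {"A": 1.0}, lower_bound=0.0, upper_bound=10.0)
    elif convention == "exchange":
        ex_a = Reaction("EX_A", {"A": -1.0}, lower_bound=-10.0, upper_bound=1000.0)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    reactions = [
        ex_a,
        Reaction("R1", {"A": -1.0, "B": 1.0}, gpr_text="g1"),
        Reaction("R2", {"A": -1.0, "C": 1.0}, gpr_text="g2"),
        Reaction("R3", {"B": -1.0, "D": 1.0}, gpr_text="g3"),
        Reaction("R4", {"C": -1.0, "D": 1.0}, gpr_text="g4"),
        Reaction("EX_D", {"D": -1.0}, objective_coefficient=1.0),
    ]
    add_reactions(model, reactions, metabolites=mets)
    if convention == "exchange":
        model.media["minimal"] = {"EX_A": (-10.0, 1000.0)}
    return model


def make_chain(n: int) -> Model:
    """A linear pathway of ``n`` internal reactions (optimum 10).

    One source exchange (ub 10), n single-gene internal steps, one sink
    exchange carrying the objective.  Every internal gene is essential and
    every FVA interval is (10, 10) at fraction 1.
    """
    if n < 1:
        raise ValueError("chain length must be >= 1")
    model = Model(id=f"chain{n}", description=f"linear chain of {n} reactions")
    met_ids = [f"M{i}" for i in range(n + 1)]
    mets = [_met(m) for m in met_ids]
    reactions = [Reaction("EX_src", {met_ids[0]: 1.0}, lower_bound=0.0, upper_bound=10.0)]
    for i in range(n):
        reactions.append(
            Reaction(f"R{i + 1}", {met_ids[i]: -1.0, met_ids[i + 1]: 1.0}, gpr_text=f"g{i + 1}")
        )
    reactions.append(Reaction("EX_sink", {met_ids[-1]: -1.0}, objective_coefficient=1.0))
    add_reactions(model, reactions, metabolites=mets)
    return model


def make_coefficient_chain() -> Model:
    """A 4-reaction chain with a coefficient-2 amplification step
    (A -> 2 B), so the optimum is 20 with source uptake capped at 10.
    Exercises non-unit stoichiometry through I/O and LP paths."""
    model = Model(id="amp_chain", description="chain with a coefficient-2 step")
    mets = [_met(m) for m in ("A", "B", "D")]
    reactions = [
        Reaction("EX_A", {"A": 1.0}, lower_bound=0.0, upper_bound=10.0),
        Reaction("R1", {"A": -1.0, "B": 2.0}, gpr_text="g1"),
        Reaction("R2", {"B": -1.0, "D": 1.0}, gpr_text="g2"),
        Reaction("EX_D", {"D": -1.0}, objective_coefficient=1.0),
    ]
    add_reactions(model, reactions, metabolites=mets)
    return model


_GPR_SHAPES = ("single", "and", "or", "and_or", "none")


def random_model(n_mets: int, n_rxns: int, seed: int = 0) -> Model:
    """A seeded random model, feasible with positive optimum by construction.

    A spanning pathway source -> M0 -> ... -> M(n_mets-1) -> sink guarantees
    a flux route of 10; the remaining reactions connect random metabolite
    pairs (random direction/reversibility) and carry random GPRs of AND/OR
    depth <= 2 over a seeded gene pool.  Same seed, same model.
    """
    if n_mets < 2:
        raise ValueError("need at least 2 metabolites")
    n_backbone = (n_mets - 1) + 2  # chain + source + sink exchanges
    if n_rxns < n_backbone:
        raise ValueError(
            f"need at least {n_backbone} reactions to span {n_mets} metabolites "
            "(chain plus two exchanges)"
        )
    rng = np.random.default_rng(seed)
    n_genes = max(3, n_rxns // 2)
    gene_pool = [f"g{i}" for i in range(n_genes)]

    def random_gpr() -> str:
        shape = rng.choice(_GPR_SHAPES, p=[0.35, 0.15, 0.2, 0.1, 0.2])
        picks = [gene_pool[i] for i in rng.choice(n_genes, size=3, replace=False)]
        if shape == "single":
            return picks[0]
        if shape == "and":
            return f"{picks[0]} and {picks[1]}"
        if shape == "or":
            return f"{picks[0]} or {picks[1]}"
        if shape == "and_or":
            return f"({picks[0]} and {picks[1]}) or {picks[2]}"
        return ""

    model = Model(id=f"random_{seed}", description=f"seeded random model (seed={seed})")
    met_ids = [f"M{i}" for i in range(n_mets)]
    mets = [_met(m) for m in met_ids]
    reactions = [Reaction("EX_src", {met_ids[0]: 1.0}, lower_bound=0.0, upper_bound=10.0)]
    for i in range(n_mets - 1):
        reactions.append(
            Reaction(
                f"R{i + 1}",
                {met_ids[i]: -1.0, met_ids[i + 1]: 1.0},
                gpr_text=random_gpr(),
            )
        )
    for j in range(n_rxns - n_backbone):
        a, b = rng.choice(n_mets, size=2, replace=False)
        reversible = bool(rng.random() < 0.3)
        reactions.append(
            Reaction(
                f"X{j + 1}",
                {met_ids[a]: -1.0, met_ids[b]: 1.0},
                lower_bound=-1000.0 if reversible else 0.0,
                upper_bound=1000.0,
                gpr_text=random_gpr(),
            )
        )
    reactions.append(Reaction("EX_sink", {met_ids[-1]: -1.0}, objective_coefficient=1.0))
    add_reactions(model, reactions, metabolites=mets)
    return model


def random_scores(
    model: Model, planted_metabolite: Optional[str] = None, seed: int = 0
) -> dict[str, float]:
    """Uniform(0,1) p-values for every gene; optionally plant a strong
    signal (p = 0.001) on one metabolite's whole gene neighborhood."""
    if not model.genes:
        raise ValueError("model has no genes to score")
    rng = np.random.default_rng(seed)
    table = {g: float(rng.uniform()) for g in model.genes}
    if planted_metabolite is not None:
        neighborhood = metabolite_neighborhood(model, planted_metabolite)
        for g in neighborhood:
            table[g] = 0.001
    return table


FIXTURE_NAMES = ("diamond", "diamond_exchange", "chain5", "amp_chain")


def load_fixture(name: str) -> Model:
    """Load a packaged fixture by name (JSON files shipped in package data)."""
    import importlib.resources as resources

    from .io import read_json

    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = resources.files("cobracore").joinpath("data", f"{name}.json")
    with resources.as_file(ref) as path:
        return read_json(str(path))
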