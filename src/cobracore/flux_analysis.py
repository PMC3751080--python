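"""Flux-analysis procedures: FBA, growth media, FVA and gene-deletion screens.

All procedures here are pure with respect to the input model: deletion and
variability screens never leave a trace in the model's bounds (they operate
on a copied LP), and :func:`apply_medium` returns a modified copy.

Gene deletions are simulated by closing reactions (``lb = ub = 0``) whose
GPR rule evaluates false under the deleted gene set — reactions are never
removed, so indices and ordering are stable.  Because the GPR grammar has no
negation, deleting more genes can only close more reactions, which makes the
deletion objective monotonically non-increasing in the deleted set.
"""

from __future__ import annotations

import math
import multiprocessing
from dataclasses import dataclass, field
from functools import partial
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .core import Medium, Model, UnknownIdError, boundary_reactions, copy_model
from .gpr import evaluate_gpr
from .solvers import (
    MAXIMIZE,
    MINIMIZE,
    OPTIMAL,
    UNBOUNDED,
    LinearProblem,
    Solution,
    build_lp,
    solve,
)

__all__ = [
    "FvaResult",
    "DeletionResult",
    "TaskOutcome",
    "optimize",
    "apply_medium",
    "flux_variability",
    "single_gene_deletion",
    "double_gene_deletion",
    "parallel_map",
    "essentiality",
    "synthetic_lethal_pairs",
]


def optimize(model: Model, solver: Optional[str] = None) -> Solution:
    """Maximize the model's objective (FBA).  Equals ``solve(build_lp(model))``."""
    if all(r.objective_coefficient == 0 for r in model.reactions.values()):
        raise ValueError(
            "model has no objective: set objective_coefficient on a reaction "
            "(typically the biomass or target exchange reaction)"
        )
    return solve(build_lp(model), solver=solver)


def apply_medium(model: Model, medium: Medium) -> Model:
    """Return a copy of the model with boundary conditions set to a medium.

    Exchange reactions listed in the medium receive the given
    ``(lower, upper)`` bounds; every other boundary reaction has its lower
    bound closed to 0 (no uptake) with the upper bound untouched.  Internal
    reactions are never modified.
    """
    boundary = boundary_reactions(model)
    for rid in medium:
        if rid not in model.reactions:
            raise UnknownIdError(f"medium references unknown reaction {rid!r}")
        if rid not in boundary:
            raise ValueError(
                f"medium reaction {rid!r} is not a boundary reaction "
                "(it touches more than one metabolite)"
            )
    out = copy_model(model)
    for rid in boundary:
        if rid in medium:
            lb, ub = medium[rid]
            out.reactions[rid].lower_bound = float(lb)
            out.reactions[rid].upper_bound = float(ub)
        else:
            out.reactions[rid].lower_bound = 0.0
    return out


# --------------------------------------------------------------------------
# parallel execution contract
# --------------------------------------------------------------------------


@dataclass
class TaskOutcome:
    """Result of one task: exactly one of ``value`` / ``error`` is set."""

    value: object = None
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


class _Guarded:
    """Picklable wrapper capturing task exceptions as TaskOutcome errors."""

    def __init__(self, func: Callable):
        self.func = func

    def __call__(self, task) -> TaskOutcome:
        try:
            return TaskOutcome(value=self.func(task))
        except Exception as exc:  # noqa: BLE001 - contract: record, continue
            return TaskOutcome(error=f"{type(exc).__name__}: {exc}")


def parallel_map(func: Callable, tasks: Iterable, n_workers: int = 1) -> list[TaskOutcome]:
    """Apply ``func`` to independent tasks, optionally across processes.

    Results come back in task order and are identical to sequential
    execution for any ``n_workers >= 1``; a failing task records its error
    without affecting the others.  ``n_workers=1`` is exactly the sequential
    path (no processes spawned).  Chunk size is ``ceil(len(tasks)/n_workers)``.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    tasks = list(tasks)
    guarded = _Guarded(func)
    if n_workers == 1 or len(tasks) <= 1:
        return [guarded(t) for t in tasks]
    chunksize = math.ceil(len(tasks) / n_workers)
    ctx = multiprocessing.get_context("fork")
    with ctx.Pool(n_workers) as pool:
        return pool.map(guarded, tasks, chunksize=chunksize)


# --------------------------------------------------------------------------
# flux variability analysis
# --------------------------------------------------------------------------


@dataclass
class FvaResult:
    """Per-reaction attainable flux range while the objective is held at
    (a fraction of) its optimum."""

    ranges: dict[str, tuple[float, float]]
    fraction_of_optimum: float
    objective_value: float

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        return self.ranges[reaction_id]

    def __iter__(self):
        return iter(self.ranges)


def _fva_one(lp: LinearProblem, solver: Optional[str], reaction_id: str) -> tuple[float, float]:
    j = lp.variable_ids.index(reaction_id)
    obj = np.zeros(len(lp.variable_ids))
    obj[j] = 1.0
    sub = lp.copy()
    sub.objective = obj
    out = []
    for sense in (MINIMIZE, MAXIMIZE):
        sol = solve(sub, sense_override=sense, solver=solver)
        if sol.status == OPTIMAL:
            out.append(sol.objective_value)
        elif sol.status == UNBOUNDED:
            out.append(-math.inf if sense == MINIMIZE else math.inf)
        else:
            raise RuntimeError(
                f"FVA subproblem for {reaction_id!r} ({sense}) returned {sol.status}"
            )
    return out[0], out[1]


def flux_variability(
    model: Model,
    fraction_of_optimum: float = 1.0,
    reactions: Optional[Sequence[str]] = None,
    solver: Optional[str] = None,
    n_workers: int = 1,
) -> FvaResult:
    """Flux variability analysis.

    First maximizes the model objective to get z*, then, with the extra
    constraint ``c . v >= fraction_of_optimum * z*``, minimizes and maximizes
    each requested reaction's flux.  The inequality (rather than pinning the
    objective exactly) matches the usual tolerance semantics and makes the
    ranges at smaller fractions supersets of those at fraction 1.
    """
    if not 0 < fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    baseline = optimize(model, solver=solver)
    if baseline.status != OPTIMAL:
        raise RuntimeError(f"baseline FBA is {baseline.status}; FVA undefined")
    z_star = baseline.objective_value
    lp = build_lp(model)
    # c.v >= f*z*  encoded as  -c.v <= -f*z*
    lp.add_inequality(-lp.objective, -fraction_of_optimum * z_star)
    if reactions is None:
        reactions = list(model.reactions)
    else:
        for rid in reactions:
            if rid not in model.reactions:
                raise UnknownIdError(f"unknown reaction id {rid!r}")
        reactions = list(reactions)
    outcomes = parallel_map(partial(_fva_one, lp, solver), reactions, n_workers=n_workers)
    ranges: dict[str, tuple[float, float]] = {}
    for rid, outcome in zip(reactions, outcomes):
        if not outcome.ok:
            raise RuntimeError(f"FVA failed for {rid!r}: {outcome.error}")
        ranges[rid] = outcome.value
    return FvaResult(ranges=ranges, fraction_of_optimum=fraction_of_optimum, objective_value=z_star)


# --------------------------------------------------------------------------
# gene deletions
# --------------------------------------------------------------------------


@dataclass
class DeletionResult:
    """Deletion screen outcome.

    ``results`` maps a gene id (single screen) or a sorted gene-id tuple
    (double screen, including the diagonal ``(g, g)``) to
    ``(status, objective)``; ``objective`` is ``None`` unless optimal.
    """

    results: dict = field(default_factory=dict)
    baseline: float = 0.0

    def objective(self, key) -> Optional[float]:
        return self.results[key][1]

    def status(self, key) -> str:
        return self.results[key][0]


def _deletion_objective(
    lp: LinearProblem,
    gpr_by_reaction: dict,
    solver: Optional[str],
    deleted: frozenset,
) -> tuple[str, Optional[float]]:
    closed = [
        j
        for j, rid in enumerate(lp.variable_ids)
        if not evaluate_gpr(gpr_by_reaction[rid], deleted)
    ]
    sub = lp.copy()
    for j in closed:
        sub.lb[j] = 0.0
        sub.ub[j] = 0.0
    sol = solve(sub, solver=solver)
    return sol.status, sol.objective_value


def _screen(
    model: Model,
    deletion_sets: list[frozenset],
    solver: Optional[str],
    n_workers: int,
) -> tuple[list[tuple[str, Optional[float]]], float]:
    baseline = optimize(model, solver=solver)
    if baseline.status != OPTIMAL:
        raise RuntimeError(f"baseline FBA is {baseline.status}; deletion screen undefined")
    lp = build_lp(model)
    gpr_by_reaction = {rid: rxn.gpr for rid, rxn in model.reactions.items()}
    func = partial(_deletion_objective, lp, gpr_by_reaction, solver)
    outcomes = parallel_map(func, deletion_sets, n_workers=n_workers)
    results = []
    for dset, outcome in zip(deletion_sets, outcomes):
        if not outcome.ok:
            raise RuntimeError(f"deletion {set(dset)} failed: {outcome.error}")
        results.append(outcome.value)
    return results, baseline.objective_value


def _check_genes(model: Model, genes: Optional[Sequence[str]]) -> list[str]:
    if genes is None:
        return list(model.genes)
    for g in genes:
        if g not in model.genes:
            raise UnknownIdError(f"unknown gene id {g!r}")
    return list(genes)


def single_gene_deletion(
    model: Model,
    genes: Optional[Sequence[str]] = None,
    solver: Optional[str] = None,
    n_workers: int = 1,
) -> DeletionResult:
    """Knock out each gene in turn and record the resulting FBA optimum."""
    gene_list = _check_genes(model, genes)
    sets = [frozenset({g}) for g in gene_list]
    results, baseline = _screen(model, sets, solver, n_workers)
    return DeletionResult(
        results={g: res for g, res in zip(gene_list, results)}, baseline=baseline
    )


def double_gene_deletion(
    model: Model,
    genes_1: Optional[Sequence[str]] = None,
    genes_2: Optional[Sequence[str]] = None,
    solver: Optional[str] = None,
    n_workers: int = 1,
) -> DeletionResult:
    """Knock out every unordered pair from ``genes_1`` x ``genes_2``.

    Each unordered pair is computed once; the diagonal ``(g, g)`` equals the
    single-gene deletion of ``g``.  Keys are sorted 2-tuples.
    """
    list_1 = _check_genes(model, genes_1)
    list_2 = _check_genes(model, genes_2) if genes_2 is not None else list_1
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for g in list_1:
        for h in list_2:
            key = tuple(sorted((g, h)))
            if key not in seen:
                seen.add(key)
                pairs.append(key)
    sets = [frozenset(p) for p in pairs]
    results, baseline = _screen(model, sets, solver, n_workers)
    return DeletionResult(
        results={p: res for p, res in zip(pairs, results)}, baseline=baseline
    )


def essentiality(
    result: DeletionResult,
    threshold_fraction: float = 0.01,
    baseline: Optional[float] = None,
) -> dict:
    """Classify each deletion as essential (True) or not.

    A deletion is essential when its objective falls below
    ``threshold_fraction * baseline``; non-optimal statuses (no feasible
    growth state) are essential by definition.
    """
    base = result.baseline if baseline is None else baseline
    if base <= 0:
        raise ValueError("baseline objective must be positive to classify essentiality")
    cutoff = threshold_fraction * base
    out = {}
    for key, (status, value) in result.results.items():
        out[key] = (status != OPTIMAL) or (value < cutoff)
    return out


def synthetic_lethal_pairs(
    double_result: DeletionResult,
    single_result: DeletionResult,
    threshold_fraction: float = 0.01,
) -> set[tuple[str, str]]:
    """Pairs lethal jointly but not individually (diagonal excluded)."""
    single_ess = essentiality(single_result, threshold_fraction)
    double_ess = essentiality(double_result, threshold_fraction)
    out = set()
    for (g, h), lethal in double_ess.items():
        if g == h or not lethal:
            continue
        if not single_ess.get(g, False) and not single_ess.get(h, False):
            out.add((g, h))
    return out
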