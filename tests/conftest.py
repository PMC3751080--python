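"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re

import numpy as np
import pytest
from scipy.optimize import linprog

from cobracore import fixtures as fx
from cobracore.core import Model, to_array_view
from cobracore.gpr import GprExpression, make_node, gene_node


@pytest.fixture
def diamond() -> Model:
    return fx.make_diamond()


@pytest.fixture
def diamond_exchange() -> Model:
    return fx.make_diamond(convention="exchange")


@pytest.fixture
def chain5() -> Model:
    return fx.make_chain(5)


@pytest.fixture
def amp_chain() -> Model:
    return fx.make_coefficient_chain()


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

_IDENT_RE = re.compile(r"[A-Za-z0-9._-]+")


def eval_gpr_text(text: str, deleted: set[str]) -> bool:
    """Brute-force GPR oracle: substitute boolean literals into the rule
    text and let Python's own and/or semantics evaluate it.  Completely
    independent of the package's parser and evaluator."""
    if not text.strip():
        return True

    def repl(m: re.Match) -> str:
        word = m.group()
        if word.lower() in ("and", "or"):
            return word.lower()
        return "False" if word in deleted else "True"

    return bool(eval(_IDENT_RE.sub(repl, text)))  # noqa: S307 - test oracle


def fba_oracle(model: Model, extra_closed: set[str] = frozenset(), sense: str = "max"):
    """Independent FBA via a direct scipy.linprog call on the array view.

    Returns (status, objective) with status in {optimal, infeasible,
    unbounded, failed}.  ``extra_closed`` reaction ids get bounds (0, 0).
    """
    view = to_array_view(model)
    lb, ub, c = view.lb.copy(), view.ub.copy(), view.c
    for rid in extra_closed:
        j = view.col_index[rid]
        lb[j] = ub[j] = 0.0
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=view.S,
        b_eq=np.zeros(view.S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
    return status, (float(sign * res.fun) if res.status == 0 else None)


def deletion_oracle(model: Model, deleted: set[str]):
    """Exhaustive independent deletion FBA: re-evaluate every reaction's
    GPR text with the text-substitution oracle and run the direct LP."""
    closed = {
        rid
        for rid, rxn in model.reactions.items()
        if not eval_gpr_text(rxn.gpr_text, deleted)
    }
    return fba_oracle(model, extra_closed=closed)


def fva_oracle(model: Model, fraction: float):
    """Per-reaction brute-force FVA with an independent LP formulation:
    the objective-retention constraint is appended as an explicit row."""
    view = to_array_view(model)
    base_status, z_star = fba_oracle(model)
    assert base_status == "optimal"
    n = view.S.shape[1]
    A_ub = -view.c.reshape(1, -1)
    b_ub = np.array([-fraction * z_star])
    bounds = list(zip(view.lb, view.ub))
    out = {}
    for rid, j in view.col_index.items():
        obj = np.zeros(n)
        obj[j] = 1.0
        lo = linprog(obj, A_eq=view.S, b_eq=np.zeros(view.S.shape[0]),
                     A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        hi = linprog(-obj, A_eq=view.S, b_eq=np.zeros(view.S.shape[0]),
                     A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        assert lo.status == 0 and hi.status == 0
        out[rid] = (float(lo.fun), float(-hi.fun))
    return out


def random_gpr_ast(rng: np.random.Generator, n_genes: int, depth: int = 3) -> GprExpression:
    """Seeded random GPR tree over genes a0..a{n_genes-1}."""
    if depth == 0 or rng.random() < 0.4:
        return gene_node(f"a{rng.integers(n_genes)}")
    kind = "AND" if rng.random() < 0.5 else "OR"
    n_children = int(rng.integers(2, 4))
    children = [random_gpr_ast(rng, n_genes, depth - 1) for _ in range(n_children)]
    return make_node(kind, children)
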