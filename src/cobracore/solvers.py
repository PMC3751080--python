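"""Linear-programming layer: model -> LP translation and pluggable backends.

Flux balance analysis is the linear program

    maximize    c . v
    subject to  S . v = 0          (steady-state mass conservation)
                lb <= v <= ub      (flux bounds / medium)

Backends are registered by name and selected by priority; all must normalize
their status codes to {optimal, infeasible, unbounded, failed} and agree on
the optimal objective value to within the configured tolerance.  Flux vectors
are NOT comparable across backends: underdetermined problems have alternate
optima, so only the objective value and feasibility are part of the contract.

Bounds are used exactly as given — the conventional magnitude 1000 is kept
finite and never promoted to infinity, so an unbounded status can only arise
from explicitly infinite bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import Model, to_array_view

__all__ = [
    "LinearProblem",
    "Solution",
    "SolverConfigurationError",
    "build_lp",
    "solve",
    "register_solver",
    "list_solvers",
    "get_config",
    "load_config",
]

MAXIMIZE = "maximize"
MINIMIZE = "minimize"

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
FAILED = "failed"


class SolverConfigurationError(RuntimeError):
    """No usable solver, or an unknown solver was requested."""


#: Global solver configuration.  ``tolerance`` is the feasibility/optimality
#: tolerance used throughout (tests, invariants, backend agreement).
_CONFIG: dict = {"tolerance": 1e-6, "solver_priority": []}


def get_config() -> dict:
    return _CONFIG


def load_config(path: str) -> dict:
    """Load solver settings from a YAML or ``key=value`` file.

    Recognized keys: ``tolerance`` (float), ``solver_priority``
    (list or comma-separated names).
    """
    import yaml

    with open(path) as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = None
    if not isinstance(data, dict):
        data = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, value = line.partition("=")
            data[key.strip()] = value.strip()
    if "tolerance" in data:
        _CONFIG["tolerance"] = float(data["tolerance"])
    if "solver_priority" in data:
        pri = data["solver_priority"]
        if isinstance(pri, str):
            pri = [p.strip() for p in pri.split(",") if p.strip()]
        _CONFIG["solver_priority"] = list(pri)
    return _CONFIG


@dataclass
class LinearProblem:
    """A flux LP: one variable per reaction, one equality row per metabolite,
    optional extra inequality rows (``A_ub . v <= b_ub``, used by FVA)."""

    variable_ids: list[str]
    lb: np.ndarray
    ub: np.ndarray
    objective: np.ndarray
    sense: str = MAXIMIZE
    A_eq: Optional[sparse.csr_matrix] = None
    b_eq: Optional[np.ndarray] = None
    constraint_ids: list[str] = field(default_factory=list)
    A_ub: Optional[sparse.csr_matrix] = None
    b_ub: Optional[np.ndarray] = None

    def copy(self) -> "LinearProblem":
        return LinearProblem(
            variable_ids=list(self.variable_ids),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            objective=self.objective.copy(),
            sense=self.sense,
            A_eq=None if self.A_eq is None else self.A_eq.copy(),
            b_eq=None if self.b_eq is None else self.b_eq.copy(),
            constraint_ids=list(self.constraint_ids),
            A_ub=None if self.A_ub is None else self.A_ub.copy(),
            b_ub=None if self.b_ub is None else self.b_ub.copy(),
        )

    def add_inequality(self, coefficients: np.ndarray, rhs: float) -> None:
        """Append one row ``coefficients . v <= rhs``."""
        row = sparse.csr_matrix(np.asarray(coefficients, dtype=float).reshape(1, -1))
        if self.A_ub is None:
            self.A_ub = row
            self.b_ub = np.array([rhs], dtype=float)
        else:
            self.A_ub = sparse.vstack([self.A_ub, row], format="csr")
            self.b_ub = np.append(self.b_ub, rhs)


@dataclass
class Solution:
    """Normalized solver result.  ``objective_value`` and ``fluxes`` are
    present iff ``status == "optimal"``."""

    status: str
    objective_value: Optional[float] = None
    fluxes: Optional[dict[str, float]] = None
    solver_name: str = ""

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


def build_lp(model: Model, sense: str = MAXIMIZE) -> LinearProblem:
    """Translate a model into its steady-state flux LP.

    The equality constraint matrix is exactly the model's stoichiometric
    matrix (insertion order); bounds and objective come from the reactions.
    """
    if not model.reactions:
        raise ValueError("cannot build an LP from a model with zero reactions")
    view = to_array_view(model)
    return LinearProblem(
        variable_ids=view.reaction_ids,
        lb=view.lb.copy(),
        ub=view.ub.copy(),
        objective=view.c.copy(),
        sense=sense,
        A_eq=view.S.tocsr(),
        b_eq=np.zeros(view.S.shape[0]),
        constraint_ids=view.metabolite_ids,
    )


# --------------------------------------------------------------------------
# backends
# --------------------------------------------------------------------------


class ScipyLinprogBackend:
    """HiGHS via ``scipy.optimize.linprog``."""

    name = "scipy"

    def available(self) -> bool:
        return True

    def solve(self, problem: LinearProblem, sense: str) -> Solution:
        sign = -1.0 if sense == MAXIMIZE else 1.0
        bounds = list(zip(problem.lb, problem.ub))
        res = linprog(
            sign * problem.objective,
            A_eq=problem.A_eq,
            b_eq=problem.b_eq,
            A_ub=problem.A_ub,
            b_ub=problem.b_ub,
            bounds=bounds,
            method="highs",
        )
        if res.status == 0:
            fluxes = dict(zip(problem.variable_ids, (float(x) for x in res.x)))
            return Solution(OPTIMAL, float(sign * res.fun), fluxes, self.name)
        if res.status == 2:
            return Solution(INFEASIBLE, solver_name=self.name)
        if res.status == 3:
            return Solution(UNBOUNDED, solver_name=self.name)
        return Solution(FAILED, solver_name=self.name)


class GlpkBackend:
    """GLPK simplex via swiglpk."""

    name = "glpk"

    def available(self) -> bool:
        try:
            import swiglpk  # noqa: F401
        except ImportError:
            return False
        return True

    def solve(self, problem: LinearProblem, sense: str) -> Solution:
        import swiglpk as glp

        n_var = len(problem.variable_ids)
        n_eq = 0 if problem.A_eq is None else problem.A_eq.shape[0]
        n_ub = 0 if problem.A_ub is None else problem.A_ub.shape[0]
        lp = glp.glp_create_prob()
        try:
            glp.glp_add_cols(lp, n_var)
            for j in range(n_var):
                self._set_bounds(glp, lp, j + 1, problem.lb[j], problem.ub[j], col=True)
                glp.glp_set_obj_coef(lp, j + 1, float(problem.objective[j]))
            glp.glp_set_obj_dir(lp, glp.GLP_MAX if sense == MAXIMIZE else glp.GLP_MIN)
            if n_eq + n_ub:
                glp.glp_add_rows(lp, n_eq + n_ub)
                entries: list[tuple[int, int, float]] = []
                if n_eq:
                    coo = problem.A_eq.tocoo()
                    for i, j, v in zip(coo.row, coo.col, coo.data):
                        entries.append((int(i) + 1, int(j) + 1, float(v)))
                    for i in range(n_eq):
                        rhs = float(problem.b_eq[i])
                        glp.glp_set_row_bnds(lp, i + 1, glp.GLP_FX, rhs, rhs)
                if n_ub:
                    coo = problem.A_ub.tocoo()
                    for i, j, v in zip(coo.row, coo.col, coo.data):
                        entries.append((n_eq + int(i) + 1, int(j) + 1, float(v)))
                    for i in range(n_ub):
                        rhs = float(problem.b_ub[i])
                        glp.glp_set_row_bnds(lp, n_eq + i + 1, glp.GLP_UP, 0.0, rhs)
                nnz = len(entries)
                ia = glp.intArray(nnz + 1)
                ja = glp.intArray(nnz + 1)
                ar = glp.doubleArray(nnz + 1)
                for k, (i, j, v) in enumerate(entries, start=1):
                    ia[k] = i
                    ja[k] = j
                    ar[k] = v
                glp.glp_load_matrix(lp, nnz, ia, ja, ar)
            params = glp.glp_smcp()
            glp.glp_init_smcp(params)
            params.msg_lev = glp.GLP_MSG_OFF
            ret = glp.glp_simplex(lp, params)
            if ret != 0:
                return Solution(FAILED, solver_name=self.name)
            status = glp.glp_get_status(lp)
            if status == glp.GLP_OPT:
                fluxes = {
                    rid: float(glp.glp_get_col_prim(lp, j + 1))
                    for j, rid in enumerate(problem.variable_ids)
                }
                return Solution(OPTIMAL, float(glp.glp_get_obj_val(lp)), fluxes, self.name)
            if status in (glp.GLP_INFEAS, glp.GLP_NOFEAS):
                return Solution(INFEASIBLE, solver_name=self.name)
            if status == glp.GLP_UNBND:
                return Solution(UNBOUNDED, solver_name=self.name)
            return Solution(FAILED, solver_name=self.name)
        finally:
            glp.glp_delete_prob(lp)

    @staticmethod
    def _set_bounds(glp, lp, index: int, lb: float, ub: float, col: bool) -> None:
        lo_inf = not np.isfinite(lb)
        up_inf = not np.isfinite(ub)
        if lo_inf and up_inf:
            kind, lo, up = glp.GLP_FR, 0.0, 0.0
        elif lo_inf:
            kind, lo, up = glp.GLP_UP, 0.0, float(ub)
        elif up_inf:
            kind, lo, up = glp.GLP_LO, float(lb), 0.0
        elif lb == ub:
            kind, lo, up = glp.GLP_FX, float(lb), float(ub)
        else:
            kind, lo, up = glp.GLP_DB, float(lb), float(ub)
        glp.glp_set_col_bnds(lp, index, kind, lo, up)


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

_SOLVERS: dict[str, object] = {}


def register_solver(name: str, backend) -> None:
    """Register a backend under ``name``; duplicate names are rejected."""
    if name in _SOLVERS:
        raise ValueError(f"solver {name!r} already registered")
    _SOLVERS[name] = backend


def list_solvers(available_only: bool = False) -> list[str]:
    names = list(_SOLVERS)
    if available_only:
        names = [n for n in names if _SOLVERS[n].available()]
    return names


def _pick_solver(name: Optional[str]):
    if name is not None:
        if name not in _SOLVERS:
            raise SolverConfigurationError(
                f"solver {name!r} not registered; installed backends: "
                f"{list_solvers(available_only=True)}"
            )
        backend = _SOLVERS[name]
        if not backend.available():
            raise SolverConfigurationError(
                f"solver {name!r} is not available; installed backends: "
                f"{list_solvers(available_only=True)}"
            )
        return backend
    priority = _CONFIG["solver_priority"] or list(_SOLVERS)
    for cand in priority:
        if cand in _SOLVERS and _SOLVERS[cand].available():
            return _SOLVERS[cand]
    raise SolverConfigurationError(
        f"no available LP solver; registered: {list(_SOLVERS)}"
    )


def solve(
    problem: LinearProblem,
    sense_override: Optional[str] = None,
    solver: Optional[str] = None,
) -> Solution:
    """Solve an LP with the requested (or highest-priority available) backend."""
    sense = sense_override or problem.sense
    if sense not in (MAXIMIZE, MINIMIZE):
        raise ValueError(f"unknown sense {sense!r}")
    backend = _pick_solver(solver)
    return backend.solve(problem, sense)


register_solver("scipy", ScipyLinprogBackend())
register_solver("glpk", GlpkBackend())
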