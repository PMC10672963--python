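"""Condition-specific flux estimation.

The flux state for a condition is the solution of a flux balance analysis
problem with a small quadratic flux-length penalty:

    max  c.v - eps * ||v||^2
    s.t. S.v = 0,  lb <= v <= ub

with eps ("flux_length_penalty") defaulting to 1e-6.  The linear term
drives the stated objective (biomass or ATP production); the strictly
concave quadratic term selects, among alternative optima of the linear
program, the flux vector of minimal Euclidean length — the parsimonious
state a cell would realise with the least enzyme expenditure.  Because
the quadratic term makes the objective strictly concave, the optimum on
the bounded feasible set is unique, which also makes every downstream
pathway deterministic.

The QP is solved with OSQP (ADMM with solution polishing, so the returned
point satisfies the KKT system to near machine precision); the auxiliary
linear programs (growth maximization) use scipy's HiGHS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .errors import ConditionError, InfeasibleError, SolverError, UnboundedError
from .model import ConditionSpec, ModelNetwork

logger = logging.getLogger(__name__)

#: |v| below this is treated as zero when collecting active reactions.
DEFAULT_ZERO_TOLERANCE = 1e-9

#: Steady-state residual the solution must satisfy.
STEADY_STATE_TOLERANCE = 1e-6


@dataclass
class FluxProblem:
    """A fully specified QP: model + bounds + linear objective + penalty."""

    model: ModelNetwork
    condition: ConditionSpec
    c: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    F_scale: float = 1e-6

    def __post_init__(self) -> None:
        n = len(self.model.reactions)
        if not (len(self.c) == len(self.lb) == len(self.ub) == n):
            raise ValueError("objective/bounds length mismatch with model")
        if self.F_scale <= 0:
            raise ValueError("F_scale must be > 0")


@dataclass
class FluxState:
    """A solved flux vector for one condition."""

    v: np.ndarray
    objective_value: float
    condition_name: str
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE
    reaction_ids: list[str] = field(default_factory=list)

    def flux(self, reaction_id: str) -> float:
        return float(self.v[self.reaction_ids.index(reaction_id)])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"reaction_id": self.reaction_ids, "flux": self.v}
        ).to_csv(path, sep="\t", index=False)


def apply_condition(
    model: ModelNetwork, condition: ConditionSpec
) -> FluxProblem:
    """Impose a condition's exchange bounds and growth constraint.

    Exchange bounds overwrite the model's bounds for the named reactions.
    A growth constraint with value ``"max"`` is resolved here by a linear
    maximization of the growth reaction (quadratic penalty excluded), whose
    optimum is then installed as the constraint value.  The returned
    problem's linear objective has a single nonzero entry at the
    condition's objective reaction.
    """
    lb, ub = model.bounds_arrays()
    for rid, (lo, hi) in condition.exchange_bounds.items():
        try:
            j = model.reaction_index(rid)
        except Exception:
            valid = ", ".join(model.exchange_ids)
            raise ConditionError(
                f"condition {condition.name!r}: unknown exchange reaction "
                f"{rid!r}; valid exchange ids: {valid}"
            ) from None
        lb[j], ub[j] = float(lo), float(hi)

    if condition.objective_reaction:
        j_obj = model.reaction_index(condition.objective_reaction)
    else:
        raise ConditionError(
            f"condition {condition.name!r} has no objective reaction"
        )

    gc = condition.growth_constraint
    if gc is not None:
        jg = model.reaction_index(gc.reaction_id)
        value = gc.value
        if value == "max":
            value = _lp_maximize(model.S, lb, ub, jg)
            # back off by a relative hair so the QP stays strictly feasible
            value -= 1e-9 * max(1.0, abs(value))
            logger.info(
                "condition %s: growth %s maximized to %.6f",
                condition.name, gc.reaction_id, value,
            )
        value = float(value)
        if gc.kind == "fixed":
            lb[jg] = ub[jg] = value
        else:
            lb[jg] = value

    c = np.zeros(len(model.reactions))
    c[j_obj] = 1.0
    return FluxProblem(
        model=model, condition=condition, c=c, lb=lb, ub=ub,
        F_scale=condition.flux_length_penalty,
    )


def _lp_maximize(
    S: sp.spmatrix, lb: np.ndarray, ub: np.ndarray, j: int
) -> float:
    """max v_j subject to S.v = 0 and bounds (HiGHS)."""
    n = S.shape[1]
    c = np.zeros(n)
    c[j] = -1.0
    res = linprog(
        c, A_eq=S.tocsr(), b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    if res.status == 2:
        raise InfeasibleError(
            "flux problem infeasible: steady state S.v=0 cannot be met "
            "within the reaction bounds (check exchange bounds and any "
            "growth constraint)"
        )
    if res.status == 3:
        raise UnboundedError(
            "flux problem unbounded: add finite bounds to the exchange "
            "reactions"
        )
    if res.status != 0:
        raise SolverError(f"LP solver failed: {res.message}")
    return float(-res.fun)


def solve_flux_state(problem: FluxProblem) -> FluxState:
    """Solve the penalized FBA problem and return its unique optimum.

    A linear pre-solve (HiGHS) classifies infeasible/unbounded problems
    with an actionable message; the QP itself is solved by the sparse
    primal-dual interior-point method in :mod:`metpath._qp`, whose
    final active-set polish returns exact zeros for reactions resting
    on their bounds and a steady-state residual around 1e-10.
    """
    from ._qp import solve_box_qp

    S = problem.model.S.tocsc()
    m, n = S.shape
    j_obj = int(np.argmax(problem.c != 0.0))
    _lp_maximize(S, problem.lb, problem.ub, j_obj)  # feasibility check

    res = solve_box_qp(
        S,
        np.zeros(m),
        problem.c,
        problem.F_scale,
        problem.lb,
        problem.ub,
    )
    if res.status == "max_iter" and not res.polished:
        raise SolverError(
            f"condition {problem.condition.name!r}: interior-point QP "
            f"stopped after {res.iterations} iterations with primal "
            f"residual {res.primal_residual:.2e}"
        )
    if not res.polished:
        logger.warning(
            "condition %s: QP polish rejected; near-zero fluxes may "
            "carry solver noise", problem.condition.name,
        )
    v = res.v
    resid = np.abs(S @ v).max() if m else 0.0
    if resid > STEADY_STATE_TOLERANCE:
        raise SolverError(
            f"steady-state residual {resid:.2e} exceeds "
            f"{STEADY_STATE_TOLERANCE:.0e}"
        )
    v = np.clip(v, problem.lb, problem.ub)
    obj = float(problem.c @ v - problem.F_scale * (v @ v))
    return FluxState(
        v=v,
        objective_value=obj,
        condition_name=problem.condition.name,
        reaction_ids=[r.id for r in problem.model.reactions],
    )


def active_reactions(
    state: FluxState, tolerance: float | None = None
) -> set[str]:
    """Reaction ids carrying flux: {r : |v_r| > tolerance}."""
    tol = state.zero_tolerance if tolerance is None else tolerance
    if tol <= 0:
        raise ValueError("tolerance must be > 0")
    return {
        rid
        for rid, flux in zip(state.reaction_ids, state.v)
        if abs(flux) > tol
    }


def estimate_flux_state(
    model: ModelNetwork, condition: ConditionSpec
) -> FluxState:
    """Convenience: ``solve_flux_state(apply_condition(model, condition))``."""
    return solve_flux_state(apply_condition(model, condition))
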