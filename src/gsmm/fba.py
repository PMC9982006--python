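"""Linear-programming core: FBA, FVA and robustness analysis.

All solves go through :func:`scipy.optimize.linprog` (HiGHS). The problem is
always

    optimize   c' v
    subject to S v = 0,  lb <= v <= ub,

optionally with the extra row ``c_obj' v >= fraction * optimum`` for
variability analysis. Only objective values are contractual: with degenerate
alternate optima the returned flux vector is one representative vertex.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from gsmm.core import MetabolicModel, build_stoichiometric_matrix

#: Feasibility/optimality tolerance handed to the solver.
LP_TOLERANCE = 1e-9
#: Relative tolerance for detecting the plateau of a robustness curve.
PLATEAU_TOLERANCE = 1e-3


class SolverStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


class InfeasibleProblemError(RuntimeError):
    """Raised when an analysis requires a feasible base problem and has none."""


@dataclass
class FluxSolution:
    status: SolverStatus
    objective_value: Optional[float]
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == SolverStatus.OPTIMAL


@dataclass
class RobustnessCurve:
    """Objective optimum as a function of one reaction's fixed flux."""

    control_reaction_id: str
    objective_reaction_id: str
    control_values: list[float]
    objective_values: list[float]
    plateau_onset: float


class _LpProblem:
    """Cached S matrix and bound arrays for repeated solves on one model."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.reaction_ids = model.reaction_ids()
        self.index = {rid: j for j, rid in enumerate(self.reaction_ids)}
        self.S = build_stoichiometric_matrix(model).tocsc()
        self.n = len(self.reaction_ids)

    def bounds_array(self) -> list[tuple[float, float]]:
        return [self.model.reactions[rid].bounds() for rid in self.reaction_ids]

    def solve(
        self,
        objective: dict[str, float],
        direction: str = "max",
        extra_A_ub: Optional[sparse.spmatrix] = None,
        extra_b_ub: Optional[np.ndarray] = None,
        bounds_override: Optional[dict[str, tuple[float, float]]] = None,
    ) -> FluxSolution:
        c = np.zeros(self.n)
        for rid, coef in objective.items():
            c[self.index[rid]] = coef
        sign = -1.0 if direction == "max" else 1.0
        bounds = self.bounds_array()
        if bounds_override:
            for rid, bb in bounds_override.items():
                bounds[self.index[rid]] = bb
        res = linprog(
            sign * c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=extra_A_ub,
            b_ub=extra_b_ub,
            bounds=bounds,
            method="highs",
            options={
                "primal_feasibility_tolerance": LP_TOLERANCE,
                "dual_feasibility_tolerance": LP_TOLERANCE,
            },
        )
        if res.status == 0:
            fluxes = dict(zip(self.reaction_ids, (float(x) for x in res.x)))
            value = float(c @ res.x)
            return FluxSolution(SolverStatus.OPTIMAL, value, fluxes)
        if res.status == 3:
            return FluxSolution(SolverStatus.UNBOUNDED, None, {})
        return FluxSolution(SolverStatus.INFEASIBLE, None, {})


def fba(
    model: MetabolicModel,
    objective_reaction_id: Optional[str] = None,
    direction: str = "max",
) -> FluxSolution:
    """Flux balance analysis: optimize one reaction's flux at steady state.

    Parameters
    ----------
    model:
        Validated metabolic model.
    objective_reaction_id:
        Reaction to optimize; defaults to the model's objective (typically
        the biomass pseudo-reaction, whose flux is mu in 1/h).
    direction:
        ``"max"`` or ``"min"``.

    Infeasibility or unboundedness is reported through ``status``, never as
    an exception; ``objective_value`` is defined only when optimal.
    """
    obj = objective_reaction_id or model.objective_reaction_id
    if obj is None or obj not in model.reactions:
        raise KeyError(f"objective reaction {obj!r} not in model")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    return _LpProblem(model).solve({obj: 1.0}, direction)


def fva(
    model: MetabolicModel,
    reaction_ids: Optional[Iterable[str]] = None,
    fraction_of_optimum: float = 1.0,
    objective_reaction_id: Optional[str] = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis.

    For each reaction, minimize and maximize its flux subject to the model
    objective being at least ``fraction_of_optimum`` times its FBA optimum.
    At fraction 1 the returned interval contains every optimal flux value;
    at fraction 0 only the steady-state and bound constraints act.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    obj = objective_reaction_id or model.objective_reaction_id
    problem = _LpProblem(model)
    rids = list(reaction_ids) if reaction_ids is not None else problem.reaction_ids

    A_ub = None
    b_ub = None
    if obj is not None and fraction_of_optimum > 0.0:
        base = problem.solve({obj: 1.0}, "max")
        if not base.optimal:
            raise InfeasibleProblemError(
                f"base FBA problem is {base.status.value}; cannot run FVA"
            )
        row = sparse.lil_matrix((1, problem.n))
        row[0, problem.index[obj]] = -1.0
        A_ub = row.tocsr()
        b_ub = np.array([-fraction_of_optimum * base.objective_value])

    out: dict[str, tuple[float, float]] = {}
    for rid in rids:
        lo = problem.solve({rid: 1.0}, "min", A_ub, b_ub)
        hi = problem.solve({rid: 1.0}, "max", A_ub, b_ub)
        if not (lo.optimal and hi.optimal):
            raise InfeasibleProblemError(f"FVA subproblem for {rid!r} not optimal")
        out[rid] = (lo.objective_value, hi.objective_value)
    return out


def robustness_analysis(
    model: MetabolicModel,
    control_reaction_id: str,
    n_points: int = 50,
    objective_reaction_id: Optional[str] = None,
    plateau_tolerance: float = PLATEAU_TOLERANCE,
) -> RobustnessCurve:
    """Objective optimum as the control reaction's flux sweeps its range.

    The feasible range of the control reaction is found by FVA at fraction 0,
    then fixed at ``n_points`` evenly spaced values; the objective is
    maximized at each. Points where fixing the control flux is infeasible are
    recorded with objective 0. ``plateau_onset`` is the smallest control
    value whose objective reaches ``(1 - plateau_tolerance)`` times the curve
    maximum.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    obj = objective_reaction_id or model.objective_reaction_id
    if obj is None or obj not in model.reactions:
        raise KeyError(f"objective reaction {obj!r} not in model")
    if control_reaction_id not in model.reactions:
        raise KeyError(f"control reaction {control_reaction_id!r} not in model")

    problem = _LpProblem(model)
    lo = problem.solve({control_reaction_id: 1.0}, "min")
    hi = problem.solve({control_reaction_id: 1.0}, "max")
    if not (lo.optimal and hi.optimal):
        raise InfeasibleProblemError(
            f"control reaction {control_reaction_id!r} has no feasible range"
        )
    vmin, vmax = lo.objective_value, hi.objective_value
    if abs(vmax - vmin) < 1e-12:
        raise InfeasibleProblemError(
            f"control reaction {control_reaction_id!r} has an empty feasible range"
        )

    control_values = list(np.linspace(vmin, vmax, n_points))
    objective_values: list[float] = []
    for v in control_values:
        sol = problem.solve(
            {obj: 1.0}, "max", bounds_override={control_reaction_id: (v, v)}
        )
        objective_values.append(sol.objective_value if sol.optimal else 0.0)

    peak = max(objective_values)
    onset = control_values[-1]
    for v, f in zip(control_values, objective_values):
        if f >= (1.0 - plateau_tolerance) * peak:
            onset = v
            break
    return RobustnessCurve(
        control_reaction_id=control_reaction_id,
        objective_reaction_id=obj,
        control_values=control_values,
        objective_values=objective_values,
        plateau_onset=onset,
    )
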