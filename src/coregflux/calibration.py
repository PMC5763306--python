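"""Calibration of the condition-specific softplus offset theta.

Given an observed growth rate v_obs, theta is chosen to maximize

    J(theta) = -ln(|v_obs - v_sim(theta)| / v_obs),

which peaks where the simulated biomass flux v_sim matches the observation.
The search evaluates J on a uniform 10-point grid over (-10, 10) and then
refines around the best grid point with deterministic golden-section search
(growth is monotone in theta, so J is unimodal).  When plain FBA itself
cannot reach v_obs — the feasible growth ceiling is below the observation —
no theta can help and the result is flagged ``fba_underestimates``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .types import FluxSolution

__all__ = ["CalibrationResult", "calibration_objective", "calibrate_theta"]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
ERROR_FLOOR = 1e-9  # relative-error floor inside the log


def calibration_objective(v_obs: float, v_sim: float) -> float:
    """-ln(|v_obs - v_sim| / v_obs) with the relative error floored at 1e-9.

    Larger is better; the floor keeps the objective finite at an exact
    match.  ``v_obs`` must be positive.
    """
    if not v_obs > 0:
        raise ValueError(f"observed growth must be positive, got {v_obs}")
    rel = abs(v_obs - v_sim) / v_obs
    return float(-np.log(max(rel, ERROR_FLOOR)))


@dataclass
class CalibrationResult:
    theta_opt: float
    objective_trace: list[tuple[float, float, float, float]] = field(default_factory=list)
    """(theta, v_sim, objective, relative error) for every evaluation."""
    status: str = "converged"  # converged | fba_underestimates | failed
    n_calls: int = 0
    method: str = "grid+golden-section"

    @property
    def v_sim_opt(self) -> float:
        best = min(self.objective_trace, key=lambda t: abs(t[0] - self.theta_opt))
        return best[1]


def calibrate_theta(
    simulate_fn: Callable[[float], FluxSolution],
    v_obs: float,
    *,
    grid_lo: float = -10.0,
    grid_hi: float = 10.0,
    grid_n: int = 10,
    fba_objective: float | None = None,
    max_calls: int = 50,
    underestimate_tol: float = 1e-3,
) -> CalibrationResult:
    """Find theta maximizing the calibration objective.

    Parameters
    ----------
    simulate_fn
        theta -> FluxSolution for the fixed condition (the rest of the
        pipeline closed over).
    v_obs
        Observed growth rate (biomass flux), > 0.
    fba_objective
        Plain-FBA growth ceiling; evaluated as ``simulate_fn(+30)`` when not
        given (softplus bounds are effectively removed there).
    max_calls
        Total budget of ``simulate_fn`` evaluations, grid included.

    Returns
    -------
    CalibrationResult
        ``status="fba_underestimates"`` when v_obs exceeds the FBA ceiling
        beyond tolerance (theta_opt is then the best grid point);
        ``"failed"`` when every grid simulation is infeasible.
    """
    if not v_obs > 0:
        raise ValueError(f"observed growth must be positive, got {v_obs}")
    result = CalibrationResult(theta_opt=np.nan)

    def evaluate(theta: float) -> float:
        sol = simulate_fn(theta)
        result.n_calls += 1
        if sol.status != "optimal":
            obj = -np.inf
            result.objective_trace.append((theta, np.nan, obj, np.nan))
            return obj
        v_sim = sol.objective_value
        obj = calibration_objective(v_obs, v_sim)
        result.objective_trace.append((theta, v_sim, obj, abs(v_obs - v_sim) / v_obs))
        return obj

    if fba_objective is None:
        sol = simulate_fn(30.0)
        result.n_calls += 1
        fba_objective = (
            sol.objective_value if sol.status == "optimal" else -np.inf
        )

    grid = np.linspace(grid_lo, grid_hi, grid_n)
    grid_obj = np.array([evaluate(t) for t in grid])
    if not np.isfinite(grid_obj).any():
        result.status = "failed"
        return result
    best = int(np.argmax(grid_obj))
    result.theta_opt = float(grid[best])

    if fba_objective < v_obs * (1.0 - underestimate_tol):
        # growth ceiling below the observation: no theta can close the gap
        result.status = "fba_underestimates"
        return result

    # golden-section refinement on the bracket around the best grid point
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_n - 1)]
    a, b = float(lo), float(hi)
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, f2 = evaluate(x1), evaluate(x2)
    while result.n_calls < max_calls and (b - a) > 1e-12:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (b - a)
            f2 = evaluate(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLDEN * (b - a)
            f1 = evaluate(x1)
    finite = [t for t in result.objective_trace if np.isfinite(t[2])]
    best_eval = max(finite, key=lambda t: t[2])
    result.theta_opt = float(best_eval[0])
    result.status = "converged"
    return result
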